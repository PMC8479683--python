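# Methods

## Problem setting

Gene catalogs organize the genes predicted from metagenomic assemblies into
non-redundant clusters, each represented by a single sequence against which
reads are later mapped and abundances estimated.  The common construction is
greedy and length-sorted: sequences are processed longest first, and each
either joins the first cluster whose representative it matches at identity
`c` (typically 0.95) over at least `aS` (typically 0.90) of its own length,
or founds a new cluster.  Large catalogs are built in several rounds: cohort-
or collection-specific catalogs are built first, then merged by re-clustering
*only the representatives*, with all other members silently carried along.

This package implements that construction and the diagnostics that expose its
failure modes, with a synthetic-data layer that makes every failure mode
constructible with exactly known ground truth.

## Transitive clustering error

Each clustering round guarantees members lie within divergence `r = 1 - c`
of *that round's* representative, but merging rounds never re-check carried
members against the new representative.  Radii therefore compound.  For a
merge tree `T`:

- `radius(leaf with threshold c) = 1 - c`
- `radius(node with children C, merge threshold c_m) = max_{t in C} radius(t) + (1 - c_m)`
- worst member-to-member divergence (diameter) `= 2 * radius(T)`

With `c = 0.95` throughout: one merge round gives member-to-representative
divergence up to `2r = 10%` (identity 90%) and pairwise divergence up to
`4r = 20%` (identity 80%); a second merge gives `3r = 15%` (identity 85%)
and `6r = 30%` (identity 70%).

These bounds are *attained* constructively (`genecat.worst_case`): a
divergence chain whose successive members differ by exactly `r` on pairwise
disjoint substitution sets is split into cohort catalogs so that every
individual admission sits exactly at the threshold while the extreme members
compound all steps.  Because substitution sets are disjoint, per-site
divergence between chain members is exactly additive — the construction is
exact, not approximate.

## The measurement contract

All admissions and audits run through one aligner (`genecat.align`):

- **glocal mode** (default): the query is aligned end-to-end inside the
  target; leading/trailing target overhangs are free, everything else is
  penalized.  This is the admission geometry of the greedy scheme.
- Scoring: match +1, mismatch -1, gap open -2 for the first gapped column,
  -1 for each further column.  Ties prefer diagonal moves and the leftmost
  optimal end on the target, so results are fully deterministic.
- Identity is matches over alignment columns within the aligned span
  (BLAST-like).  The alternative convention, matches over the shorter
  sequence length (as used by the common greedy clustering tool), is exposed
  via `AlignmentStats.identity_shorter` and the `identity_definition` switch;
  published audits do not always state which convention they used, so both
  are available and outputs are labelled.
- Coordinates are 0-based half-open throughout.

A deliberately simple pure-Python full-matrix implementation with explicit
traceback (`oracle_align_stats`, guarded to 10^6 cells) serves as the
independent cross-check in tests; the production path is a numba-compiled
linear-memory version of the same contract plus an exact-substring fast path.

**Per-site divergence vs alignment identity.**  On highly divergent
equal-length pairs the score-optimal alignment may recover marginally more
identity than the per-site substitution fraction by opening gaps around
chance local matches (e.g. ~80.1% instead of 80.0% at a designed 20%
divergence; the effect is absent up to ~15% divergence under this scoring).
The worst-case geometry above is a statement about per-site divergence, so
bound-attainment measurements use `site_divergence` (brute-force mismatch
counting on the equal-length substitution-only constructions), with the DP
aligner reported alongside as corroboration.  Alignment-identity audits of
realistic catalogs are unaffected: there the aligner *is* the instrument.

## Synthetic data

`genecat.synth` generates every input downstream stages need:

- `mutate_to_divergence` — exactly `round(d * L)` substitutions (round
  half-up, stated once and used everywhere), at positions disjoint from a
  caller-supplied forbidden set, each to a different base.  This is the
  primitive that makes divergence additive and exact.
- `make_divergence_chain` — the worst-case construction backbone.
- `make_multispecies_family` — per species, `genes_unique` independent random
  genes plus shared families at exactly `1 - shared_identity` cross-species
  divergence (direct mutation for two species; a latent-ancestor star at
  half-divergence on disjoint sites for three or more).  Shared-gene ids sort
  the first species' copy ahead, so lexicographic tie-breaking hands it the
  representative slot — the hidden-species setup with a combinatorially exact
  hidden fraction.
- `simulate_read_pairs` — forward–reverse pairs, uniform starts, normal
  insert sizes (sd defaulting to mean/10), i.i.d. per-base substitution
  errors.  Deliberately minimal: no indel errors, no quality model, no
  platform profile.  Passing tests therefore demonstrate the *accounting*
  (assignment, multi-mapping, cross-labelling) under controlled divergence,
  not robustness to realistic sequencing noise.

All generators take one explicit seed per call and derive child seeds through
`numpy.random.SeedSequence`; identical seeds give byte-identical output.

## Clustering and merging choices

- Threshold comparisons are inclusive (`>=`); boundary fixtures at exactly
  0.95 identity are tested explicitly.
- Length ties in the processing order break lexicographically by id — the
  published descriptions are silent here, and tests exploit the rule to steer
  constructions.
- Assignment is first-fit (scan clusters in creation order) by default, with
  a best-fit mode behind `ClusteringParams(assignment="best_fit")`; which one
  the original constructions used is not documented.
- `merge_catalogs` never re-validates carried members — deliberately, since
  that is the audited mechanism; `strict=True` re-checks and evicts failures
  into singletons, and the pair of runs quantifies the transitive error.
- Representative coverage is unconstrained by default (the audited artifact
  allowing members with no mutual overlap); an optional
  `representative_coverage_threshold` closes that hole.

## Audits

- Cluster radius audits re-align every member to the representative fresh
  rather than trusting stored admission statistics, so externally supplied
  membership files are audited identically.
- Diameter (all-pairs) computation is opt-in and capped at 200 members per
  cluster to keep desk-scale runtime; histogram bins are fixed at 1%
  identity.
- Zero-overlap detection calls two members disjoint when their glocally
  matched intervals on the representative do not intersect.
- Set cover is exact (subset enumeration ascending by size, lexicographic
  within size — deterministic tie-breaking) for universes up to 20 species,
  greedy largest-coverage-first beyond, flagged as approximate.  Members with
  no qualifying hits are reported separately, never counted.
- The read mapper is an exact 21-mer seed table plus glocal extension; ties
  on alignment score make a read multi-mapped, and multi-mapped reads are not
  fractionally allocated.  A cluster's species label is its representative's
  label — exactly the visibility rule that hides species.  Pair concordance
  requires a shared target, opposite strands, and an implied insert within
  3 standard deviations of the expected mean.

## Problem sizes

Tests and the acceptance script run at desk scale by design: chain length
1000 nt for the worst-case constructions, gene families of 900 nt, ~10,000
simulated reads per species for the hidden-species recovery, 100 random
instances (n <= 30) for the clustering equivalence suite, and 200 random hit
tables for the set-cover orderings.  Catalog-release-scale figures (fractions
of below-threshold clusters in the published catalog, database-wide species
fractions, external-mapper percentages) require the original release files
and external tools and are explicitly out of scope; the corresponding metrics
are implemented and validated on the synthetic fixtures instead.

## Known limitations

- No reverse-complement search in clustering (catalog genes are assumed
  oriented); strand handling exists only in read assignment.
- The aligner has no heuristic seeding for genome-scale inputs; it targets
  gene-length sequences (~10^2–10^4 nt).
- The exact set cover is exponential in universe size and intentionally
  guarded; the greedy fallback is a ln(n)-approximation.
- Read simulation has no indel or quality model, so mapper behaviour under
  realistic error profiles is untested by construction.
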