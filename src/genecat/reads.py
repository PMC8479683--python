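"""Read assignment against catalog representatives and its failure modes.

The mapper is intentionally simple and fully specified: a fixed-length exact
seed table over the representative sequences proposes candidate targets, each
candidate is scored with the glocal aligner, and the best alignment score
wins.  Score ties across representatives make the read multi-mapped (not
fractionally allocated).  The species label a read inherits is the label of
the winning cluster's *representative* — exactly the visibility rule that
hides species whose genes never become representatives.

``crossmap_accounting`` is pure bookkeeping over three read/gene/cluster maps
and reproduces the concordant-pair crossmap quantities: among reads
concordant to genes that have a home cluster, how many land in a different
cluster than expected; among reads concordant to genes without a home
cluster, how many land in any cluster at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import align_stats
from .cluster import Catalog
from .synth import ReadPair, reverse_complement

logger = logging.getLogger(__name__)

SEED_LENGTH_DEFAULT = 21


@dataclass
class ReadAssignment:
    read_id: str
    best_targets: frozenset[str]
    assigned_species: str | None
    is_multimapped: bool
    is_concordant: bool
    true_source_id: str | None = None

    @property
    def status(self) -> str:
        if not self.best_targets:
            return "unassigned"
        return "multimapped" if self.is_multimapped else "assigned"


@dataclass
class RepresentativeIndex:
    """Exact k-mer seed table over catalog representatives."""

    catalog: Catalog
    seed_length: int = SEED_LENGTH_DEFAULT
    seeds: dict[str, list[str]] = field(init=False)

    def __post_init__(self):
        table: dict[str, set[str]] = {}
        k = self.seed_length
        for rep in self.catalog.representatives():
            for i in range(0, len(rep.bases) - k + 1):
                table.setdefault(rep.bases[i:i + k], set()).add(rep.id)
        self.seeds = {kmer: sorted(ids) for kmer, ids in table.items()}

    def candidates(self, read: str) -> list[str]:
        k = self.seed_length
        found: set[str] = set()
        for i in range(0, len(read) - k + 1):
            found.update(self.seeds.get(read[i:i + k], ()))
        return sorted(found)


def _best_hits(read: str, index: RepresentativeIndex, catalog, min_identity,
               both_strands):
    """Best-scoring representatives for one mate.

    Returns (targets, orientation_by_target, score); empty targets when no
    candidate reaches min_identity.
    """
    strands = [("+", read)]
    if both_strands:
        strands.append(("-", reverse_complement(read)))
    best_score = None
    targets: dict[str, str] = {}
    for strand, seq in strands:
        for rep_id in index.candidates(seq):
            rep = catalog.sequence_index[rep_id]
            if len(seq) > len(rep.bases):
                continue
            st = align_stats(seq, rep.bases, mode="glocal")
            if st.identity < min_identity:
                continue
            if best_score is None or st.score > best_score:
                best_score = st.score
                targets = {rep_id: strand}
            elif st.score == best_score and rep_id not in targets:
                targets[rep_id] = strand
    return targets, best_score


def assign_reads(pairs: list[ReadPair], catalog: Catalog,
                 min_identity: float = 0.95, both_strands: bool = True,
                 seed_length: int = SEED_LENGTH_DEFAULT,
                 insert_mean: int | None = None,
                 insert_sd: float | None = None,
                 index: RepresentativeIndex | None = None) -> list[ReadAssignment]:
    """Assign read pairs to catalog representatives.

    A pair's target set is the intersection of the mates' best-score target
    sets when non-empty (concordance requires a shared representative),
    otherwise the union of both mates' targets with the pair flagged
    non-concordant.  A pair is concordant when both mates hit a common
    representative on opposite strands and, when ``insert_mean`` is given,
    the implied insert is within 3 standard deviations of it.
    """
    if index is None:
        index = RepresentativeIndex(catalog, seed_length)
    elif index.catalog is not catalog:
        raise ValueError("index was built for a different catalog")
    if insert_sd is None and insert_mean is not None:
        insert_sd = max(1.0, insert_mean / 10)

    out: list[ReadAssignment] = []
    for pair in pairs:
        t1, s1 = _best_hits(pair.read1, index, catalog, min_identity, both_strands)
        t2, s2 = _best_hits(pair.read2, index, catalog, min_identity, both_strands)
        shared = {r for r in t1 if r in t2 and t1[r] != t2[r]}
        concordant = False
        if shared:
            best = shared
            if insert_mean is not None:
                ok = set()
                for rep_id in shared:
                    rep = catalog.sequence_index[rep_id]
                    a1 = align_stats(pair.read1 if t1[rep_id] == "+" else
                                     reverse_complement(pair.read1), rep.bases)
                    a2 = align_stats(pair.read2 if t2[rep_id] == "+" else
                                     reverse_complement(pair.read2), rep.bases)
                    lo = min(a1.target_interval[0], a2.target_interval[0])
                    hi = max(a1.target_interval[1], a2.target_interval[1])
                    if abs((hi - lo) - insert_mean) <= 3 * insert_sd:
                        ok.add(rep_id)
                concordant = bool(ok)
                best = ok or shared
            else:
                concordant = True
        else:
            best = set(t1) | set(t2)
        species = None
        if best:
            labels = {catalog.sequence_index[r].species for r in best}
            if len(labels) == 1:
                species = labels.pop()
        out.append(ReadAssignment(
            read_id=pair.id,
            best_targets=frozenset(best),
            assigned_species=species,
            is_multimapped=len(best) > 1,
            is_concordant=concordant,
            true_source_id=pair.source_id))
    return out


@dataclass
class SpeciesRates:
    species: str
    n_reads: int
    assignment_rate: float
    cross_label_fraction: float
    multimap_fraction: float


def assignment_rates(assignments: list[ReadAssignment],
                     truth: dict[str, str]) -> list[SpeciesRates]:
    """Per-species assignment, cross-label and multi-mapping rates.

    ``truth`` maps read id -> true species.  assignment_rate counts reads
    whose assigned label equals the truth; cross_label_fraction counts reads
    assigned a *different* label; reads with no label (unassigned, or
    multi-mapped across species) count toward neither.
    """
    per: dict[str, dict[str, int]] = {}
    for a in assignments:
        if a.read_id not in truth:
            raise KeyError(f"no truth label for read {a.read_id!r}")
        sp = truth[a.read_id]
        d = per.setdefault(sp, {"n": 0, "correct": 0, "cross": 0, "multi": 0})
        d["n"] += 1
        if a.is_multimapped:
            d["multi"] += 1
        if a.assigned_species is None:
            continue
        if a.assigned_species == sp:
            d["correct"] += 1
        else:
            d["cross"] += 1
    out = [SpeciesRates(sp, d["n"], d["correct"] / d["n"], d["cross"] / d["n"],
                        d["multi"] / d["n"])
           for sp, d in per.items()]
    out.sort(key=lambda r: r.species)
    return out


@dataclass
class CrossmapReport:
    n_concordant_to_clustered_genes: int
    fraction_to_unexpected_cluster: float
    n_concordant_to_unclustered_genes: int
    fraction_mapping_to_any_cluster: float
    n_unreconciled: int = 0


def crossmap_accounting(read_to_gene: dict[str, str],
                        read_to_cluster: dict[str, str | None],
                        gene_to_cluster: dict[str, str | None]) -> CrossmapReport:
    """Concordant-pair crossmap bookkeeping between genes and catalog clusters.

    ``read_to_gene``: reads concordant to a predicted gene -> that gene.
    ``read_to_cluster``: read -> catalog cluster it mapped to (None = none).
    ``gene_to_cluster``: gene -> its home cluster (None = unclustered gene).

    Among reads whose gene has a home cluster, reports the fraction landing in
    a *different* cluster than expected; among reads whose gene is
    unclustered, the fraction landing in any cluster.  Reads present in
    ``read_to_cluster`` but absent from ``read_to_gene`` go to a logged
    reconciliation bucket.
    """
    unreconciled = [r for r in read_to_cluster if r not in read_to_gene]
    if unreconciled:
        logger.warning("%d reads in read_to_cluster missing from read_to_gene",
                       len(unreconciled))
    n_clustered = n_unexpected = 0
    n_unclustered = n_any = 0
    for read, gene in read_to_gene.items():
        if gene not in gene_to_cluster:
            raise KeyError(f"gene {gene!r} missing from gene_to_cluster")
        expected = gene_to_cluster[gene]
        observed = read_to_cluster.get(read)
        if expected is None:
            n_unclustered += 1
            if observed is not None:
                n_any += 1
        else:
            n_clustered += 1
            if observed is not None and observed != expected:
                n_unexpected += 1
    return CrossmapReport(
        n_concordant_to_clustered_genes=n_clustered,
        fraction_to_unexpected_cluster=(n_unexpected / n_clustered
                                        if n_clustered else 0.0),
        n_concordant_to_unclustered_genes=n_unclustered,
        fraction_mapping_to_any_cluster=(n_any / n_unclustered
                                         if n_unclustered else 0.0),
        n_unreconciled=len(unreconciled))
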