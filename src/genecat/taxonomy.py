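"""Taxonomic heterogeneity of clusters: set-cover and top-hit species counts.

Given, for each cluster member, the set of species with a qualifying database
hit, two estimators of how many species a cluster contains:

* minimum set cover — the smallest set of species such that every member has
  at least one hit to a species in the set.  A conservative lower bound:
  shared genes are explained by as few species as possible.
* top hit — each member contributes the species of its single best-scoring
  hit.  The common practice, and a systematic overcount whenever near-ties
  scatter across species.

Also: the hidden-species report, which measures per species how many of its
genes are representatives of their clusters.  A gene whose cluster is
represented by another species' sequence is invisible to representative-based
read assignment; a species with hidden_fraction 1 is undetectable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .cluster import Catalog

logger = logging.getLogger(__name__)

EXACT_LIMIT_DEFAULT = 20


@dataclass
class HitTable:
    """Per-member candidate species with scores, sorted by descending score."""

    rows: dict[str, list[tuple[str, float]]]
    universe: set[str] = field(init=False)

    def __post_init__(self):
        for mid, hits in self.rows.items():
            self.rows[mid] = sorted(hits, key=lambda h: (-h[1], h[0]))
        self.universe = {sp for hits in self.rows.values() for sp, _ in hits}

    @classmethod
    def from_alignments(cls, rows, species_of, min_identity=95.0,
                        min_coverage=90.0):
        """Build from BLAST/Diamond outfmt-6-like rows.

        ``rows``: iterable of (query, subject, pct_identity, aln_length,
        bitscore); ``species_of``: subject -> species.  Query lengths are
        needed for coverage, so rows must carry (query, qlen) tuples as the
        first field or coverage filtering is skipped when qlen is None.
        """
        table: dict[str, list[tuple[str, float]]] = {}
        for q, subject, ident, aln_len, qlen, score in rows:
            table.setdefault(q, [])
            if ident < min_identity:
                continue
            if qlen is not None and 100.0 * aln_len / qlen < min_coverage:
                continue
            sp = species_of.get(subject)
            if sp is None:
                continue
            table[q].append((sp, float(score)))
        # keep only the best score per (member, species)
        for q, hits in table.items():
            best: dict[str, float] = {}
            for sp, sc in hits:
                if sp not in best or sc > best[sp]:
                    best[sp] = sc
            table[q] = list(best.items())
        return cls(table)


@dataclass
class SpeciesCountResult:
    method: str  # setcover_exact | setcover_greedy | tophit
    species: set[str]
    uncovered_members: set[str]

    @property
    def size(self) -> int:
        return len(self.species)


def _members_with_hits(hits: HitTable) -> dict[str, set[str]]:
    return {m: {sp for sp, _ in row} for m, row in hits.rows.items() if row}


def species_set_cover(hits: HitTable,
                      exact_limit: int = EXACT_LIMIT_DEFAULT) -> SpeciesCountResult:
    """Minimum set of species covering every member that has any hit.

    Exact when the species universe is small (exhaustive search over subsets
    in increasing size, lexicographic order — deterministic tie-breaking);
    greedy largest-coverage-first otherwise, flagged ``setcover_greedy``.
    Members with empty hit lists are reported as uncovered, never counted.
    """
    member_sets = _members_with_hits(hits)
    uncovered = {m for m, row in hits.rows.items() if not row}
    if not member_sets:
        return SpeciesCountResult("setcover_exact", set(), uncovered)
    universe = sorted({sp for s in member_sets.values() for sp in s})

    if len(universe) <= exact_limit:
        needed = list(member_sets.values())
        for k in range(1, len(universe) + 1):
            for combo in itertools.combinations(universe, k):
                chosen = set(combo)
                if all(s & chosen for s in needed):
                    return SpeciesCountResult("setcover_exact", chosen, uncovered)
        raise AssertionError("unreachable: full universe always covers")

    logger.warning("species universe of %d exceeds exact_limit=%d; "
                   "APPROXIMATE greedy cover", len(universe), exact_limit)
    remaining = dict(member_sets)
    chosen: set[str] = set()
    while remaining:
        counts = {sp: 0 for sp in universe}
        for s in remaining.values():
            for sp in s:
                counts[sp] += 1
        # largest coverage first, ties lexicographic
        sp = min(counts, key=lambda x: (-counts[x], x))
        chosen.add(sp)
        remaining = {m: s for m, s in remaining.items() if sp not in s}
    return SpeciesCountResult("setcover_greedy", chosen, uncovered)


def species_top_hit(hits: HitTable) -> SpeciesCountResult:
    """Distinct species when every member takes its single best-scoring hit."""
    tops: set[str] = set()
    uncovered: set[str] = set()
    for m, row in hits.rows.items():
        if not row:
            uncovered.add(m)
            continue
        tops.add(row[0][0])  # rows pre-sorted by (-score, species)
    return SpeciesCountResult("tophit", tops, uncovered)


@dataclass
class SpeciesVisibility:
    species: str
    n_genes: int
    n_representative_genes: int

    @property
    def hidden_fraction(self) -> float:
        return 1.0 - self.n_representative_genes / self.n_genes


def hidden_species_report(catalog: Catalog) -> list[SpeciesVisibility]:
    """Per-species gene counts, representative counts and hidden fractions.

    Sorted by descending hidden_fraction (worst-hidden species first), ties
    by species name.  Unlabeled sequences are tallied under ``None``-skipping:
    they are excluded from the per-species table.
    """
    rep_ids = set(catalog.representative_ids)
    genes: dict[str, int] = {}
    reps: dict[str, int] = {}
    for sid, seq in catalog.sequence_index.items():
        if seq.species is None:
            continue
        genes[seq.species] = genes.get(seq.species, 0) + 1
        if sid in rep_ids:
            reps[seq.species] = reps.get(seq.species, 0) + 1
    out = [SpeciesVisibility(sp, genes[sp], reps.get(sp, 0)) for sp in genes]
    out.sort(key=lambda v: (-v.hidden_fraction, v.species))
    return out
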