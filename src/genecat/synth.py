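"""Synthetic gene families, divergence chains and paired reads with exact ground truth.

Every generator in this module realizes divergence by substitutions only, on
explicitly tracked position sets.  Because substitution positions across
successive mutation steps are kept pairwise disjoint, per-site divergence is
*additive*: the divergence between chain members i < j equals the sum of the
step divergences between them, with no tolerance.  This is what makes the
worst-case geometry of iterative catalog merging (the 2r/4r blow-up)
constructible and measurable exactly.

Rounding convention: ``round half-up`` (0.5 rounds away from zero) everywhere
a fractional count of sites is converted to an integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LabeledSequence:
    """A nucleotide gene sequence with optional taxonomic and provenance labels.

    ``genus`` falls back to the first whitespace-delimited token of ``species``
    when not given explicitly (e.g. species ``"Escherichia coli"`` has genus
    ``"Escherichia"``).
    """

    id: str
    bases: str
    species: str | None = None
    genus: str | None = None
    family_id: str | None = None
    is_fragment: bool = False
    parent_id: str | None = None
    parent_interval: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} has empty bases")
        if self.genus is None and self.species is not None:
            object.__setattr__(self, "genus", self.species.split()[0])

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class DivergenceChain:
    """An ordered chain of sequences with exactly additive pairwise divergence."""

    members: list[LabeledSequence]
    step_divergences: list[float]
    realized_pairwise: np.ndarray
    position_sets: list[frozenset[int]] = field(default_factory=list)


@dataclass(frozen=True)
class ReadPair:
    """A simulated paired-end read with known origin.

    ``read2`` is stored reverse-complemented relative to the source strand
    (forward-reverse orientation), as a sequencer would emit it.
    """

    id: str
    read1: str
    read2: str
    source_id: str
    source_species: str | None
    insert_size: int
    start: int
    orientation: str = "FR"


class DivergenceBudgetError(ValueError):
    """Raised when the requested substitutions do not fit the free positions."""


def random_sequence(length: int, seed: int, *, id: str = "seq",
                    **labels) -> LabeledSequence:
    rng = np.random.default_rng(seed)
    bases = "".join(rng.choice(list(ALPHABET), size=length))
    return LabeledSequence(id=id, bases=bases, **labels)


def mutate_to_divergence(
    seq: LabeledSequence,
    d: float,
    forbidden_positions: frozenset[int] | set[int] = frozenset(),
    seed: int = 0,
    *,
    new_id: str | None = None,
) -> tuple[LabeledSequence, frozenset[int]]:
    """Return a copy of *seq* with exactly ``round(d*len)`` substitutions.

    Substitution positions are drawn uniformly from positions outside
    ``forbidden_positions`` and each substituted base differs from the
    original, so the gap-free per-site identity to the input is exactly
    ``1 - round(d*len)/len``.  Returns the mutated sequence and the positions
    used, so successive calls can be kept disjoint.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError(f"divergence must be in [0, 1), got {d}")
    n = len(seq)
    n_sub = round_half_up(d * n)
    free = sorted(set(range(n)) - set(forbidden_positions))
    if n_sub > len(free):
        raise DivergenceBudgetError(
            f"need {n_sub} free positions but only {len(free)} remain "
            f"(deficit {n_sub - len(free)}) in sequence {seq.id!r}"
        )
    rng = np.random.default_rng(seed)
    if n_sub == 0:
        out = seq if new_id is None else replace(seq, id=new_id)
        return out, frozenset()
    positions = rng.choice(len(free), size=n_sub, replace=False)
    chosen = frozenset(free[int(i)] for i in positions)
    bases = list(seq.bases)
    for pos in chosen:
        alternatives = [b for b in ALPHABET if b != bases[pos]]
        bases[pos] = alternatives[int(rng.integers(len(alternatives)))]
    out = replace(seq, bases="".join(bases),
                  id=seq.id if new_id is None else new_id)
    return out, chosen


def make_divergence_chain(
    length: int,
    step_divergences: list[float],
    seed: int,
    *,
    id_prefix: str = "chain",
    ids: list[str] | None = None,
) -> DivergenceChain:
    """Build a chain where member i+1 differs from member i by exactly d_i.

    All step substitution sets are pairwise disjoint, so the realized
    divergence between members i and j equals ``sum(step_divergences[i:j])``
    exactly (as a count of sites over the length).

    ``ids``, when given, names the members (used to steer tie-breaking in
    downstream length-sorted clustering).
    """
    if sum(step_divergences) > 1.0:
        raise DivergenceBudgetError(
            f"total divergence {sum(step_divergences)} exceeds 1"
        )
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(len(step_divergences) + 1)]
    if ids is None:
        ids = [f"{id_prefix}{i}" for i in range(len(step_divergences) + 1)]
    if len(ids) != len(step_divergences) + 1:
        raise ValueError("need one id per chain member")

    members = [random_sequence(length, child_seeds[0], id=ids[0])]
    used: set[int] = set()
    position_sets: list[frozenset[int]] = []
    step_counts: list[int] = []
    for i, d in enumerate(step_divergences):
        nxt, positions = mutate_to_divergence(
            members[-1], d, frozenset(used), child_seeds[i + 1], new_id=ids[i + 1]
        )
        used |= positions
        position_sets.append(positions)
        step_counts.append(len(positions))
        members.append(nxt)

    m = len(members)
    realized = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            realized[i, j] = realized[j, i] = sum(step_counts[i:j]) / length
    return DivergenceChain(members, list(step_divergences), realized, position_sets)


def make_multispecies_family(
    n_species: int,
    genes_shared: int,
    genes_unique: int,
    shared_identity: float,
    gene_length: int,
    seed: int,
    *,
    species_names: list[str] | None = None,
) -> list[LabeledSequence]:
    """Emit a labelled multi-species gene complement with controlled sharing.

    Per species: ``genes_unique`` private genes (independent random sequences,
    far from everything else) and one copy per species of each of
    ``genes_shared`` shared gene families whose inter-species divergence is
    exactly ``1 - shared_identity``.

    For two species the second copy is mutated directly from the first; for
    three or more, copies radiate from a latent ancestor at half the target
    divergence on disjoint positions, so every cross-species pair realizes the
    full divergence.

    Shared-gene ids sort by species index (``f<k>_s0...`` before ``f<k>_s1...``),
    so under lexicographic tie-breaking the first species' copy becomes the
    cluster representative — the hidden-species setup.
    """
    if not 0.0 < shared_identity <= 1.0:
        raise ValueError("shared_identity must be in (0, 1]")
    if min(n_species, genes_shared, genes_unique) < 0:
        raise ValueError("counts must be non-negative")
    delta = 1.0 - shared_identity
    if delta >= 1.0 or (n_species > 2 and n_species * round_half_up(delta / 2 * gene_length) > gene_length):
        raise DivergenceBudgetError("shared divergence budget infeasible")
    if species_names is None:
        species_names = [f"species_{chr(ord('A') + i)}" for i in range(n_species)]

    ss = np.random.SeedSequence(seed)
    out: list[LabeledSequence] = []
    for fam in range(genes_shared):
        fam_seed = ss.spawn(1)[0]
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in fam_seed.spawn(n_species + 1)]
        ancestor = random_sequence(gene_length, seeds[0], id=f"f{fam}_anc")
        used: set[int] = set()
        if n_species == 2:
            first = replace(ancestor, id=f"f{fam}_s0",
                            species=species_names[0], family_id=f"f{fam}")
            second, _ = mutate_to_divergence(ancestor, delta, seed=seeds[1],
                                             new_id=f"f{fam}_s1")
            out += [first, replace(second, species=species_names[1],
                                   family_id=f"f{fam}")]
        else:
            for sp in range(n_species):
                copy, positions = mutate_to_divergence(
                    ancestor, delta / 2, frozenset(used), seeds[sp + 1],
                    new_id=f"f{fam}_s{sp}")
                used |= positions
                out.append(replace(copy, species=species_names[sp],
                                   family_id=f"f{fam}"))
    for sp in range(n_species):
        sp_seed = ss.spawn(1)[0]
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sp_seed.spawn(genes_unique)]
        for g in range(genes_unique):
            out.append(random_sequence(
                gene_length, seeds[g], id=f"u{g}_s{sp}",
                species=species_names[sp], family_id=None))
    return out


def fragment_sequence(
    seq: LabeledSequence,
    fraction: float,
    anchor: str = "start",
    seed: int = 0,
    *,
    new_id: str | None = None,
) -> LabeledSequence:
    """Take a contiguous substring of length ``round(fraction*len)``.

    ``anchor`` places it at the start, the end, or uniformly at random.
    Provenance (parent id and 0-based half-open interval) is retained.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    frag_len = round_half_up(fraction * len(seq))
    if frag_len == 0:
        raise ValueError(f"fragment of {seq.id!r} at fraction {fraction} is empty")
    if anchor == "start":
        start = 0
    elif anchor == "end":
        start = len(seq) - frag_len
    elif anchor == "random":
        rng = np.random.default_rng(seed)
        start = int(rng.integers(0, len(seq) - frag_len + 1))
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return replace(
        seq,
        id=seq.id if new_id is None else new_id,
        bases=seq.bases[start:start + frag_len],
        is_fragment=True,
        parent_id=seq.id,
        parent_interval=(start, start + frag_len),
    )


def simulate_read_pairs(
    sources: list[LabeledSequence],
    read_length: int,
    coverage: float,
    error_rate: float,
    insert_mean: int,
    seed: int,
    *,
    insert_sd: float | None = None,
) -> list[ReadPair]:
    """Simulate forward-reverse paired reads with substitution errors.

    Per source, roughly ``coverage * len / (2 * read_length)`` pairs are drawn
    with uniform start positions and normally distributed insert sizes
    (truncated to fit).  Errors are i.i.d. per-base substitutions at
    ``error_rate``.  Sources shorter than the insert are skipped.
    The error model is deliberately minimal (no indels, no quality model):
    ground truth stays exact and additivity arguments carry over to reads.
    """
    if insert_sd is None:
        insert_sd = max(1.0, insert_mean / 10)
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    for src in sources:
        if len(src) < insert_mean or len(src) < read_length:
            import warnings
            warnings.warn(f"source {src.id!r} shorter than insert; skipped")
            continue
        n_pairs = round_half_up(coverage * len(src) / (2 * read_length))
        for k in range(n_pairs):
            insert = int(round(rng.normal(insert_mean, insert_sd)))
            insert = max(read_length, min(insert, len(src)))
            start = int(rng.integers(0, len(src) - insert + 1))
            frag = src.bases[start:start + insert]
            r1 = frag[:read_length]
            r2 = reverse_complement(frag[-read_length:])
            if error_rate > 0:
                r1 = _inject_errors(r1, error_rate, rng, base_idx)
                r2 = _inject_errors(r2, error_rate, rng, base_idx)
            pairs.append(ReadPair(
                id=f"{src.id}|p{k}", read1=r1, read2=r2,
                source_id=src.id, source_species=src.species,
                insert_size=insert, start=start))
    return pairs


def _inject_errors(read: str, rate: float, rng, base_idx) -> str:
    errs = np.nonzero(rng.random(len(read)) < rate)[0]
    if len(errs) == 0:
        return read
    bases = list(read)
    for pos in errs:
        alternatives = [b for b in ALPHABET if b != bases[pos]]
        bases[pos] = alternatives[int(rng.integers(3))]
    return "".join(bases)
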