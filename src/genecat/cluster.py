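"""Length-sorted greedy clustering and iterative catalog merging.

``greedy_cluster`` reproduces the incremental scheme used to build large gene
catalogs: sequences are processed longest first; each either joins the first
existing cluster whose representative it matches at >= c identity over >= aS
of its own length, or founds a new cluster with itself as representative.

``merge_catalogs`` reproduces the multi-round construction in which only the
*representatives* of previously built catalogs are re-clustered and every
other member silently follows its old representative into the new cluster —
without any re-check against the new representative.  That carried-over,
unchecked membership is precisely what lets the effective cluster radius grow
by (1 - c) per round: the transitive clustering error.  A ``strict`` mode
re-validates carried members and evicts failures into singleton clusters, to
quantify the difference.

``transitive_radius_bound`` computes the worst-case divergence bounds implied
by a merge tree: each round adds one admission step of radius (1 - c), so a
member can end up ``max(child radii) + (1 - c_merge)`` from its final
representative, and two co-clustered members twice that far from each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import AlignmentStats, align_stats
from .synth import LabeledSequence


@dataclass(frozen=True)
class ClusteringParams:
    """Admission thresholds for one clustering round.

    ``identity_threshold`` (c) and ``query_coverage_threshold`` (aS) follow
    the common catalog defaults of 0.95 / 0.90.  ``representative_coverage_threshold``
    is None by default — the audited construction does not constrain how much
    of the representative must be covered, which is what allows members with
    no mutual overlap.
    """

    identity_threshold: float = 0.95
    query_coverage_threshold: float = 0.90
    representative_coverage_threshold: float | None = None
    assignment: str = "first_fit"  # or "best_fit"
    identity_definition: str = "alignment_columns"  # or "shorter_sequence"

    def __post_init__(self):
        for v in (self.identity_threshold, self.query_coverage_threshold):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must be in (0, 1]")
        if self.assignment not in ("first_fit", "best_fit"):
            raise ValueError(f"unknown assignment {self.assignment!r}")

    def admits(self, stats: AlignmentStats) -> bool:
        if stats.identity_by(self.identity_definition) < self.identity_threshold:
            return False
        if stats.query_coverage < self.query_coverage_threshold:
            return False
        if (self.representative_coverage_threshold is not None
                and stats.target_coverage < self.representative_coverage_threshold):
            return False
        return True


@dataclass
class Cluster:
    representative_id: str
    members: list[tuple[str, AlignmentStats]] = field(default_factory=list)
    round_created: int = 0

    @property
    def member_ids(self) -> list[str]:
        return [m for m, _ in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MergeTree:
    """Leaf (one clustering round) or node (a merge round over child catalogs)."""

    params: ClusteringParams
    children: list["MergeTree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def radius(self) -> float:
        """Worst-case member-to-representative divergence under this tree."""
        r = 1.0 - self.params.identity_threshold
        if self.is_leaf:
            return r
        return max(c.radius() for c in self.children) + r

    def n_rounds(self) -> int:
        return 1 + (max(c.n_rounds() for c in self.children) if self.children else 0)


def leaf(params: ClusteringParams | None = None) -> MergeTree:
    return MergeTree(params or ClusteringParams())


def node(children: list[MergeTree], params: ClusteringParams | None = None) -> MergeTree:
    if not children:
        raise ValueError("merge node needs at least one child")
    return MergeTree(params or ClusteringParams(), list(children))


def transitive_radius_bound(tree: MergeTree) -> tuple[float, float]:
    """Return (member-to-representative, pairwise) worst-case divergence bounds.

    Leaf radius is 1 - c; a merge node adds its own 1 - c_merge on top of the
    deepest child.  The pairwise bound is twice the radius (two members on
    opposite sides of the representative, divergent on disjoint sites).
    Equivalent identity bounds are ``1 - bound``.
    """
    r = tree.radius()
    return r, 2.0 * r


@dataclass
class Catalog:
    clusters: list[Cluster]
    sequence_index: dict[str, LabeledSequence]
    merge_tree: MergeTree

    def cluster_of(self) -> dict[str, int]:
        """Member id -> index of its cluster."""
        out: dict[str, int] = {}
        for i, cl in enumerate(self.clusters):
            for mid, _ in cl.members:
                out[mid] = i
        return out

    @property
    def representative_ids(self) -> list[str]:
        return [c.representative_id for c in self.clusters]

    def representatives(self) -> list[LabeledSequence]:
        return [self.sequence_index[c.representative_id] for c in self.clusters]


def _sorted_for_processing(seqs: list[LabeledSequence]) -> list[LabeledSequence]:
    # longest first; ties broken lexicographically by id (documented choice)
    return sorted(seqs, key=lambda s: (-len(s), s.id))


def greedy_cluster(seqs: list[LabeledSequence],
                   params: ClusteringParams | None = None,
                   round_created: int = 0) -> Catalog:
    """Cluster sequences greedily, longest first.

    Deterministic: the processing order is internal (length, then id), so the
    result does not depend on input order.  Each member's admission alignment
    statistics are recorded on the cluster.
    """
    params = params or ClusteringParams()
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")

    index = {s.id: s for s in seqs}
    clusters: list[Cluster] = []
    for seq in _sorted_for_processing(seqs):
        chosen: tuple[int, AlignmentStats] | None = None
        for ci, cl in enumerate(clusters):
            rep = index[cl.representative_id]
            if len(seq) > len(rep):
                continue  # cannot admit a query longer than the representative
            stats = align_stats(seq, rep, mode="glocal")
            if params.admits(stats):
                if params.assignment == "first_fit":
                    chosen = (ci, stats)
                    break
                if chosen is None or stats.score > chosen[1].score:
                    chosen = (ci, stats)
        if chosen is None:
            self_stats = align_stats(seq, seq, mode="glocal")
            clusters.append(Cluster(seq.id, [(seq.id, self_stats)], round_created))
        else:
            clusters[chosen[0]].members.append((seq.id, chosen[1]))
    return Catalog(clusters, index, leaf(params))


def merge_catalogs(catalogs: list[Catalog],
                   params: ClusteringParams | None = None,
                   strict: bool = False) -> Catalog:
    """Merge catalogs by re-clustering only their representatives.

    Non-representative members follow their old representative into its new
    cluster without threshold re-checks — deliberately reproducing the audited
    multi-round construction and, with it, transitive clustering error.  With
    ``strict=True`` every carried member is re-aligned to its new
    representative and evicted into a singleton cluster when it no longer
    satisfies the round's thresholds.
    """
    params = params or ClusteringParams()
    if not catalogs:
        raise ValueError("no catalogs to merge")
    index: dict[str, LabeledSequence] = {}
    for cat in catalogs:
        for sid, seq in cat.sequence_index.items():
            if sid in index:
                raise ValueError(f"sequence id collision across catalogs: {sid!r}")
            index[sid] = seq

    round_no = max(c.merge_tree.n_rounds() for c in catalogs)
    reps = [seq for cat in catalogs for seq in cat.representatives()]
    rep_catalog = greedy_cluster(reps, params, round_created=round_no)

    # carry every old cluster's members into the cluster its rep landed in
    old_cluster_by_rep = {c.representative_id: c for cat in catalogs for c in cat.clusters}
    merged: list[Cluster] = []
    evicted: list[Cluster] = []
    for mcl in rep_catalog.clusters:
        new = Cluster(mcl.representative_id, [], round_no)
        new_rep = index[mcl.representative_id]
        for rep_id, rep_stats in mcl.members:
            old = old_cluster_by_rep[rep_id]
            for mid, admission in old.members:
                if mid == rep_id:
                    # the old representative's own admission in this round
                    new.members.append((mid, rep_stats))
                    continue
                if strict:
                    restats = align_stats(index[mid], new_rep, mode="glocal")
                    if not params.admits(restats):
                        self_stats = align_stats(index[mid], index[mid], mode="glocal")
                        evicted.append(Cluster(mid, [(mid, self_stats)], round_no))
                        continue
                new.members.append((mid, admission))
        merged.append(new)
    merged.extend(evicted)
    tree = node([c.merge_tree for c in catalogs], params)
    return Catalog(merged, index, tree)


def brute_force_cluster(seqs: list[LabeledSequence],
                        params: ClusteringParams | None = None):
    """Independent reference for greedy clustering (tests only).

    Re-derives the processing order and re-scans clusters in creation order
    with explicit alignments; returns frozenset-of-frozensets membership plus
    the representative map, for comparison against :func:`greedy_cluster`.
    """
    params = params or ClusteringParams()
    order = sorted(seqs, key=lambda s: (-len(s.bases), s.id))
    reps: list[LabeledSequence] = []
    membership: list[list[str]] = []
    for s in order:
        placed = False
        for k, rep in enumerate(reps):
            if len(s.bases) > len(rep.bases):
                continue
            st = align_stats(s.bases, rep.bases, mode="glocal")
            if (st.identity_by(params.identity_definition) >= params.identity_threshold
                    and st.query_coverage >= params.query_coverage_threshold):
                membership[k].append(s.id)
                placed = True
                break
        if not placed:
            reps.append(s)
            membership.append([s.id])
    rep_of = {m: reps[k].id for k, group in enumerate(membership) for m in group}
    return frozenset(frozenset(g) for g in membership), rep_of
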