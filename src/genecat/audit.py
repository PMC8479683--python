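"""Per-cluster and per-catalog fidelity diagnostics.

A cluster built with an identity threshold c is often presumed to hold every
member within 1 - c of its representative.  After multi-round merging that
presumption fails, and clusters can also contain members placed on disjoint
parts of a long representative (no shared sequence at all).  This module
re-measures, from the sequences themselves:

* radius — the worst member-to-representative identity,
* diameter — the worst member-to-member identity (opt-in, quadratic),
* length spread between representative and shortest member,
* how much of the representative the shortest member covers,
* zero-overlap member pairs — members whose matched intervals on the
  representative are disjoint.

Audits always re-align members to the representative rather than trusting
stored admission statistics, so externally supplied membership files can be
audited identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .align import align_stats
from .cluster import Catalog, Cluster, ClusteringParams
from .synth import LabeledSequence

PAIRWISE_SIZE_CAP = 200
HIST_BIN_WIDTH = 0.01  # 1% identity bins


@dataclass
class ClusterAudit:
    cluster_id: str
    size: int
    min_member_identity_to_rep: float
    min_pairwise_identity: float | None
    rep_length: int
    shortest_member_length: int
    length_diff: int
    length_diff_fraction_of_rep: float
    rep_fraction_aligned_by_shortest: float
    zero_overlap_member_pairs: int


@dataclass
class AuditReport:
    cluster_audits: list[ClusterAudit]
    identity_threshold: float
    n_clusters_total: int
    min_cluster_size: int
    fraction_below_threshold: float | None
    fraction_below_half: float | None
    histogram: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters_audited(self) -> int:
        return len(self.cluster_audits)


def _intervals_disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[1] <= b[0] or b[1] <= a[0]


def audit_cluster(cluster: Cluster,
                  sequences: dict[str, LabeledSequence],
                  compute_pairwise: bool = False,
                  identity_definition: str = "alignment_columns") -> ClusterAudit:
    """Re-measure one cluster against its representative.

    Two members count as a zero-overlap pair when their glocally matched
    intervals on the representative are disjoint — the signature of the
    domain-concatenation artifact in long representatives.
    """
    if not cluster.members:
        raise ValueError("cannot audit an empty cluster")
    missing = [m for m in cluster.member_ids if m not in sequences]
    if missing:
        raise KeyError(f"member sequences missing from index: {missing}")
    rep = sequences[cluster.representative_id]

    min_ident = 1.0
    intervals: list[tuple[int, int]] = []
    shortest = rep
    shortest_stats = None
    for mid in cluster.member_ids:
        member = sequences[mid]
        st = align_stats(member, rep, mode="glocal")
        ident = st.identity_by(identity_definition)
        min_ident = min(min_ident, ident)
        intervals.append(st.target_interval)
        if shortest_stats is None or len(member) < len(shortest):
            shortest, shortest_stats = member, st

    zero_overlap = sum(
        1 for a, b in itertools.combinations(intervals, 2)
        if _intervals_disjoint(a, b))

    min_pair: float | None = None
    if compute_pairwise and cluster.size <= PAIRWISE_SIZE_CAP:
        min_pair = 1.0
        for a, b in itertools.combinations(cluster.member_ids, 2):
            sa, sb = sequences[a], sequences[b]
            q, t = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            st = align_stats(q, t, mode="glocal")
            min_pair = min(min_pair, st.identity_by(identity_definition))

    return ClusterAudit(
        cluster_id=cluster.representative_id,
        size=cluster.size,
        min_member_identity_to_rep=min_ident,
        min_pairwise_identity=min_pair,
        rep_length=len(rep),
        shortest_member_length=len(shortest),
        length_diff=len(rep) - len(shortest),
        length_diff_fraction_of_rep=(len(rep) - len(shortest)) / len(rep),
        rep_fraction_aligned_by_shortest=shortest_stats.target_coverage,
        zero_overlap_member_pairs=zero_overlap)


def audit_catalog(catalog: Catalog,
                  params: ClusteringParams | None = None,
                  compute_pairwise: bool = False,
                  min_cluster_size: int = 1,
                  identity_definition: str = "alignment_columns") -> AuditReport:
    """Aggregate cluster audits over a catalog.

    Reports the fraction of (size-filtered) clusters whose worst member falls
    below the admission threshold, the fraction at or below 50% identity, and
    a 1%-bin histogram of worst identities.
    """
    params = params or catalog.merge_tree.params
    c = params.identity_threshold
    audits = [
        audit_cluster(cl, catalog.sequence_index, compute_pairwise,
                      identity_definition)
        for cl in catalog.clusters if cl.size >= min_cluster_size
    ]
    if audits:
        below = sum(1 for a in audits if a.min_member_identity_to_rep < c)
        below_half = sum(1 for a in audits if a.min_member_identity_to_rep <= 0.50)
        frac_below = below / len(audits)
        frac_half = below_half / len(audits)
    else:
        frac_below = frac_half = None
    hist: dict[str, int] = {}
    for a in audits:
        bin_lo = int(a.min_member_identity_to_rep / HIST_BIN_WIDTH) * HIST_BIN_WIDTH
        key = f"{bin_lo:.2f}"
        hist[key] = hist.get(key, 0) + 1
    return AuditReport(
        cluster_audits=audits,
        identity_threshold=c,
        n_clusters_total=len(catalog.clusters),
        min_cluster_size=min_cluster_size,
        fraction_below_threshold=frac_below,
        fraction_below_half=frac_half,
        histogram=dict(sorted(hist.items())))


@dataclass
class FamilyDivergence:
    family_id: str
    representative_id: str
    n_members: int
    min_identity_to_representative: float


def gene_family_divergence(
    families: dict[str, list[LabeledSequence]],
    threshold: float = 0.95,
    identity_definition: str = "alignment_columns",
) -> tuple[list[FamilyDivergence], float]:
    """Worst within-family identity to the longest member, per family.

    For each ground-truth gene family the longest sequence (ties by id) plays
    the representative; the minimum identity of any member against it is the
    family's effective clustering radius.  Returns per-family records and the
    fraction of families whose worst identity meets ``threshold`` — i.e. the
    fraction a single-round catalog at that threshold could keep intact.
    """
    records: list[FamilyDivergence] = []
    for fid, members in families.items():
        if not members:
            raise ValueError(f"family {fid!r} is empty")
        rep = sorted(members, key=lambda s: (-len(s), s.id))[0]
        worst = 1.0
        for m in members:
            if m.id == rep.id:
                continue
            st = align_stats(m, rep, mode="glocal")
            worst = min(worst, st.identity_by(identity_definition))
        records.append(FamilyDivergence(fid, rep.id, len(members), worst))
    if records:
        frac = sum(1 for r in records
                   if r.min_identity_to_representative >= threshold) / len(records)
    else:
        frac = float("nan")
    return records, frac
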