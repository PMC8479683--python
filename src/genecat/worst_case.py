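"""Constructive attainment of the transitive clustering error bounds.

The analytic side (:func:`genecat.cluster.transitive_radius_bound`) says a
member may drift ``max(child radii) + (1 - c)`` in divergence from its final
representative per merge round, and two co-clustered members twice that.
This module *realizes* those worst cases: substitution-only divergence chains
(disjoint mutation sets, hence exactly additive per-site divergence) arranged
so that every individual admission honours the thresholds while the final
cluster attains the bound exactly.

With c = 0.95 (radius r = 0.05):

* two rounds (three cohort catalogs merged once): member-to-representative
  divergence 2r = 10% (identity 90%), pairwise 4r = 20% (identity 80%);
* three rounds (that catalog merged once more with a fresh single-round
  catalog): 3r = 15% (identity 85%) and 6r = 30% (identity 70%).

Chain members all share one length, so per-site (Hamming) divergence is the
exact measurement; the score-based DP aligner is reported alongside (it can
recover marginally higher identity on the most divergent pairs by gapped
realignment around chance matches).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .align import align_stats, site_divergence
from .cluster import (Catalog, ClusteringParams, greedy_cluster,
                      merge_catalogs, transitive_radius_bound)
from .synth import make_divergence_chain


@dataclass
class AttainmentResult:
    """Analytic bounds vs measured worst cases for one constructed merge."""

    bound_member_divergence: float
    bound_pairwise_divergence: float
    measured_member_divergence: float
    measured_pairwise_divergence: float
    dp_min_member_identity: float
    dp_min_pairwise_identity: float
    all_admissions_within_thresholds: bool
    catalog: Catalog

    @property
    def member_attained(self) -> bool:
        # the bound accumulates binary representation noise from (1 - c) sums;
        # the measured side is an exact ratio of site counts
        return math.isclose(self.measured_member_divergence,
                            self.bound_member_divergence, abs_tol=1e-9)

    @property
    def pairwise_attained(self) -> bool:
        return math.isclose(self.measured_pairwise_divergence,
                            self.bound_pairwise_divergence, abs_tol=1e-9)


def _measure(catalog: Catalog, params: ClusteringParams) -> AttainmentResult:
    bound_member, bound_pair = transitive_radius_bound(catalog.merge_tree)
    worst_member = 0.0
    worst_pair = 0.0
    dp_member = 1.0
    dp_pair = 1.0
    admissions_ok = True
    for cl in catalog.clusters:
        rep = catalog.sequence_index[cl.representative_id]
        for mid, admission in cl.members:
            if not params.admits(admission):
                admissions_ok = False
            member = catalog.sequence_index[mid]
            worst_member = max(worst_member, site_divergence(member, rep))
            dp_member = min(dp_member, align_stats(member, rep).identity)
        for a, b in itertools.combinations(cl.member_ids, 2):
            sa, sb = catalog.sequence_index[a], catalog.sequence_index[b]
            worst_pair = max(worst_pair, site_divergence(sa, sb))
            dp_pair = min(dp_pair, align_stats(sa, sb).identity)
    return AttainmentResult(
        bound_member_divergence=bound_member,
        bound_pairwise_divergence=bound_pair,
        measured_member_divergence=worst_member,
        measured_pairwise_divergence=worst_pair,
        dp_min_member_identity=dp_member,
        dp_min_pairwise_identity=dp_pair,
        all_admissions_within_thresholds=admissions_ok,
        catalog=catalog)


def two_round_worst_case(length: int = 1000, seed: int = 1,
                         identity_threshold: float = 0.95) -> AttainmentResult:
    """One merge of three single-round catalogs, pushed to the 2r/4r extremes.

    A 4-step chain ``m0—m1—m2—m3—m4`` (each step r = 1 - c, disjoint sites)
    is split so that round one clusters {m1: m0} and {m3: m4} with m2 alone;
    the merge round then clusters the representatives m1, m2, m3 under m2.
    m0 ends 2r from the meta-representative and 4r from m4.  Ids are chosen
    so the length-tie lexicographic ordering yields exactly this shape.
    """
    r = 1.0 - identity_threshold
    params = ClusteringParams(identity_threshold=identity_threshold)
    # chain index -> id: m2 must found the merge cluster, m1/m3 its joiners
    ids = ["d", "b", "a", "c", "e"]  # m0..m4
    chain = make_divergence_chain(length, [r] * 4, seed, ids=ids)
    m0, m1, m2, m3, m4 = chain.members
    cohorts = [
        greedy_cluster([m1, m0], params),
        greedy_cluster([m2], params),
        greedy_cluster([m3, m4], params),
    ]
    merged = merge_catalogs(cohorts, params)
    return _measure(merged, params)


def three_round_worst_case(length: int = 1000, seed: int = 1,
                           identity_threshold: float = 0.95) -> AttainmentResult:
    """A two-round catalog merged once more with a fresh leaf: 3r/6r extremes.

    A 6-step chain ``mA—mid1—r1—T—r2—mid2—mB``: round one forms
    {mid1: mA} and {mid2: mB} plus singletons; the first merge forms
    {r1: mid1, mA} and {r2: mid2, mB}; the final merge clusters r1 and r2
    under T.  mA and mB each end 3r from T, and 6r from each other on
    disjoint substitution sets.
    """
    r = 1.0 - identity_threshold
    params = ClusteringParams(identity_threshold=identity_threshold)
    # chain order [mA, mid1, r1, T, r2, mid2, mB]
    ids = ["f", "d", "b", "a", "c", "e", "g"]
    chain = make_divergence_chain(length, [r] * 6, seed, ids=ids)
    mA, mid1, r1, T, r2, mid2, mB = chain.members
    cohorts = [
        greedy_cluster([mid1, mA], params),
        greedy_cluster([r1, mid2, mB], params),
        greedy_cluster([r2], params),
    ]
    first_merge = merge_catalogs(cohorts, params)
    top = merge_catalogs([first_merge, greedy_cluster([T], params)], params)
    return _measure(top, params)
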