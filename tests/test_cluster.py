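"""Greedy clustering semantics, the merge mechanism, and the transitive-error
radius bounds with their constructive attainment."""

import numpy as np
import pytest

from genecat import (ClusteringParams, align_stats, greedy_cluster, leaf,
                     make_divergence_chain, merge_catalogs,
                     mutate_to_divergence, node, site_divergence,
                     three_round_worst_case, transitive_radius_bound,
                     two_round_worst_case)
from genecat.cluster import brute_force_cluster

from conftest import random_seq


def _family_instance(seed, n=20, length_lo=60, length_hi=140):
    """Random sequences in a few mutation families: clusterable structure."""
    rng = np.random.default_rng(seed)
    seqs = []
    k = 0
    while len(seqs) < n:
        base = random_seq(int(rng.integers(length_lo, length_hi)),
                          seed=int(rng.integers(2**31)), sid=f"g{k}")
        seqs.append(base)
        k += 1
        for _ in range(int(rng.integers(0, 4))):
            if len(seqs) >= n:
                break
            d = float(rng.uniform(0.0, 0.12))
            variant, _ = mutate_to_divergence(base, d, seed=int(rng.integers(2**31)),
                                              new_id=f"g{k}")
            seqs.append(variant)
            k += 1
    return seqs


class TestGreedyCluster:
    def test_single_sequence(self):
        s = random_seq(200, seed=1, sid="only")
        cat = greedy_cluster([s])
        assert len(cat.clusters) == 1
        assert cat.clusters[0].representative_id == "only"
        assert cat.clusters[0].member_ids == ["only"]

    def test_boundary_identity_is_inclusive(self):
        rep = random_seq(1000, seed=2, sid="a")
        member, _ = mutate_to_divergence(rep, 0.05, seed=3, new_id="b")
        cat = greedy_cluster([rep, member], ClusteringParams(0.95, 0.90))
        assert len(cat.clusters) == 1  # exactly 0.95 admits

    def test_below_threshold_splits(self):
        rep = random_seq(1000, seed=4, sid="a")
        member, _ = mutate_to_divergence(rep, 0.06, seed=5, new_id="b")
        cat = greedy_cluster([rep, member], ClusteringParams(0.95, 0.90))
        assert len(cat.clusters) == 2  # 0.94 identity is rejected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reference(self, seed):
        seqs = _family_instance(seed, n=25)
        cat = greedy_cluster(seqs)
        got = frozenset(frozenset(c.member_ids) for c in cat.clusters)
        want, rep_of = brute_force_cluster(seqs)
        assert got == want
        for c in cat.clusters:
            for m in c.member_ids:
                assert rep_of[m] == c.representative_id

    def test_order_independence(self):
        seqs = _family_instance(11, n=18)
        a = greedy_cluster(seqs)
        rng = np.random.default_rng(0)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        b = greedy_cluster(shuffled)
        assert [c.representative_id for c in a.clusters] == \
               [c.representative_id for c in b.clusters]
        assert [c.member_ids for c in a.clusters] == \
               [c.member_ids for c in b.clusters]

    def test_duplicate_ids_rejected(self):
        s = random_seq(100, seed=1, sid="dup")
        with pytest.raises(ValueError, match="dup"):
            greedy_cluster([s, s])

    def test_single_round_radius_guarantee(self):
        seqs = _family_instance(21, n=30)
        params = ClusteringParams(0.95, 0.90)
        cat = greedy_cluster(seqs, params)
        for cl in cat.clusters:
            rep = cat.sequence_index[cl.representative_id]
            for mid, _ in cl.members:
                st = align_stats(cat.sequence_index[mid], rep)
                assert st.identity >= params.identity_threshold - 1e-12


class TestRadiusBounds:
    def test_single_round(self):
        member, pair = transitive_radius_bound(leaf(ClusteringParams(0.95)))
        assert member == pytest.approx(0.05)
        assert pair == pytest.approx(0.10)

    def test_one_merge_of_three_cohorts(self):
        tree = node([leaf(), leaf(), leaf()])
        member, pair = transitive_radius_bound(tree)
        assert member == pytest.approx(0.10)  # identity 90%
        assert pair == pytest.approx(0.20)    # identity 80%

    def test_second_merge_with_fresh_leaf(self):
        inner = node([leaf(), leaf(), leaf()])
        tree = node([leaf(), inner])
        member, pair = transitive_radius_bound(tree)
        assert member == pytest.approx(0.15)  # identity 85%
        assert pair == pytest.approx(0.30)    # identity 70%

    def test_mixed_thresholds(self):
        tree = node([leaf(ClusteringParams(0.90)), leaf(ClusteringParams(0.95))],
                    ClusteringParams(0.98))
        member, _ = transitive_radius_bound(tree)
        assert member == pytest.approx(0.10 + 0.02)


class TestMergeCatalogs:
    def test_identical_singletons_collapse(self):
        s = random_seq(300, seed=6, sid="x")
        twin = type(s)(id="y", bases=s.bases)
        a = greedy_cluster([s])
        b = greedy_cluster([twin])
        merged = merge_catalogs([a, b])
        assert len(merged.clusters) == 1

    def test_distant_representatives_stay_apart(self):
        cats = [greedy_cluster([random_seq(200, seed=s, sid=f"r{s}")])
                for s in range(4)]
        merged = merge_catalogs(cats)
        assert len(merged.clusters) == 4

    def test_id_collision_rejected(self):
        s = random_seq(100, seed=7, sid="same")
        with pytest.raises(ValueError, match="collision"):
            merge_catalogs([greedy_cluster([s]), greedy_cluster([s])])

    def test_figure_one_geometry_realized(self):
        """One merge round co-clusters chain ends at 4r = 20% divergence."""
        res = two_round_worst_case(length=1000, seed=7)
        assert len(res.catalog.clusters) == 1
        assert res.all_admissions_within_thresholds
        assert res.measured_member_divergence == pytest.approx(0.10)
        assert res.measured_pairwise_divergence == pytest.approx(0.20)
        assert res.member_attained and res.pairwise_attained

    def test_strict_mode_restores_radius(self):
        params = ClusteringParams(0.95, 0.90)
        loose = two_round_worst_case(length=1000, seed=5)
        # default mode: the radius blows up to 2r
        assert loose.measured_member_divergence > 0.05 + 1e-9

        # rebuild the same scenario with strict re-validation
        ids = ["d", "b", "a", "c", "e"]
        chain = make_divergence_chain(1000, [0.05] * 4, 5, ids=ids)
        m0, m1, m2, m3, m4 = chain.members
        cohorts = [greedy_cluster([m1, m0], params),
                   greedy_cluster([m2], params),
                   greedy_cluster([m3, m4], params)]
        strict = merge_catalogs(cohorts, params, strict=True)
        for cl in strict.clusters:
            rep = strict.sequence_index[cl.representative_id]
            for mid, _ in cl.members:
                member = strict.sequence_index[mid]
                assert site_divergence(member, rep) <= 0.05 + 1e-9

    @pytest.mark.parametrize("seed", range(6))
    def test_bound_validity_random_merges(self, seed):
        """No member ever exceeds the analytic radius, whatever the merge."""
        rng = np.random.default_rng(seed)
        params = ClusteringParams(0.95, 0.90)
        cats = []
        for c in range(3):
            steps = [float(rng.uniform(0.0, 0.05)) for _ in range(3)]
            chain = make_divergence_chain(
                400, steps, int(rng.integers(2**31)),
                ids=[f"c{c}m{i}" for i in range(len(steps) + 1)])
            cats.append(greedy_cluster(chain.members, params))
        merged = merge_catalogs(cats, params)
        bound, _ = transitive_radius_bound(merged.merge_tree)
        for cl in merged.clusters:
            rep = merged.sequence_index[cl.representative_id]
            for mid, _ in cl.members:
                d = site_divergence(merged.sequence_index[mid], rep)
                assert d <= bound + 1e-9


class TestThreeRoundConstruction:
    def test_attains_three_r_and_six_r(self):
        res = three_round_worst_case(length=1000, seed=3)
        assert len(res.catalog.clusters) == 1
        assert res.all_admissions_within_thresholds
        assert res.measured_member_divergence == pytest.approx(0.15)
        assert res.measured_pairwise_divergence == pytest.approx(0.30)
        assert res.member_attained and res.pairwise_attained
        assert res.catalog.merge_tree.n_rounds() == 3
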