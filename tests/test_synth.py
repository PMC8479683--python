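"""Ground-truth guarantees of the synthetic generators: exact substitution
counts, additive divergence on disjoint sites, provenance, reproducibility."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecat import (DivergenceBudgetError, fragment_sequence,
                     make_divergence_chain, make_multispecies_family,
                     mutate_to_divergence, oracle_align_stats,
                     simulate_read_pairs)
from genecat.synth import reverse_complement, round_half_up

from conftest import hamming, random_seq

pytestmark = []


class TestMutateToDivergence:
    @pytest.mark.parametrize("length,d", [(100, 0.05), (100, 0.0), (250, 0.1),
                                          (1000, 0.033), (37, 0.5)])
    def test_exact_substitution_count(self, length, d):
        seq = random_seq(length, seed=1)
        out, positions = mutate_to_divergence(seq, d, seed=2)
        expected = round_half_up(d * length)
        assert hamming(seq.bases, out.bases) == expected
        assert len(positions) == expected
        assert all(seq.bases[p] != out.bases[p] for p in positions)

    def test_zero_divergence_is_identity(self):
        seq = random_seq(80, seed=5)
        out, positions = mutate_to_divergence(seq, 0.0, seed=9)
        assert out.bases == seq.bases
        assert positions == frozenset()

    def test_disjoint_chained_calls_are_additive(self):
        seq = random_seq(1000, seed=4)
        step1, pos1 = mutate_to_divergence(seq, 0.05, seed=10)
        step2, pos2 = mutate_to_divergence(step1, 0.05, pos1, seed=11)
        assert not (pos1 & pos2)
        assert hamming(seq.bases, step2.bases) == 100  # exactly 0.10

    def test_insufficient_free_positions_reports_deficit(self):
        seq = random_seq(10, seed=1)
        with pytest.raises(DivergenceBudgetError, match="deficit"):
            mutate_to_divergence(seq, 0.5, frozenset(range(8)), seed=1)

    @given(length=st.integers(20, 300),
           d=st.floats(0.0, 0.5), seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_divergence_always_exact(self, length, d, seed):
        seq = random_seq(length, seed=seed % 997)
        out, _ = mutate_to_divergence(seq, d, seed=seed)
        assert hamming(seq.bases, out.bases) == round_half_up(d * length)


class TestDivergenceChain:
    def test_four_step_chain_reaches_twenty_percent(self, chain4):
        m0, m4 = chain4.members[0], chain4.members[4]
        assert hamming(m0.bases, m4.bases) == 200
        assert chain4.realized_pairwise[0, 4] == pytest.approx(0.20)

    def test_realized_matrix_matches_brute_force(self, chain4):
        n = len(chain4.members)
        for i in range(n):
            for j in range(n):
                got = hamming(chain4.members[i].bases, chain4.members[j].bases)
                assert got / 1000 == chain4.realized_pairwise[i, j]

    def test_empty_steps_single_member(self):
        chain = make_divergence_chain(500, [], seed=2)
        assert len(chain.members) == 1

    def test_uneven_steps(self):
        chain = make_divergence_chain(200, [0.05, 0.10], seed=3)
        assert hamming(chain.members[0].bases, chain.members[2].bases) == 30

    def test_budget_guard(self):
        with pytest.raises(DivergenceBudgetError):
            make_divergence_chain(100, [0.6, 0.6], seed=1)

    def test_reproducible_and_seed_sensitive(self):
        a = make_divergence_chain(300, [0.05, 0.05], seed=42)
        b = make_divergence_chain(300, [0.05, 0.05], seed=42)
        c = make_divergence_chain(300, [0.05, 0.05], seed=43)
        assert [m.bases for m in a.members] == [m.bases for m in b.members]
        assert [m.bases for m in a.members] != [m.bases for m in c.members]


class TestMultispeciesFamily:
    def test_two_species_shared_identity_exact(self):
        seqs = make_multispecies_family(2, 10, 5, 0.96, 900, seed=11)
        assert len(seqs) == 2 * 10 + 2 * 5
        by_family = {}
        for s in seqs:
            if s.family_id is not None:
                by_family.setdefault(s.family_id, []).append(s)
        assert len(by_family) == 10
        for members in by_family.values():
            a, b = members
            assert a.species != b.species
            st_ = oracle_align_stats(a, b, mode="global")
            assert st_.identity == pytest.approx(0.96, abs=1e-12)

    def test_single_species_unique_only(self):
        seqs = make_multispecies_family(1, 0, 3, 0.9, 500, seed=8)
        assert len(seqs) == 3
        assert all(s.family_id is None for s in seqs)
        # unrelated: nowhere near the clustering threshold
        assert hamming(seqs[0].bases, seqs[1].bases) > 200

    def test_identity_one_gives_identical_copies(self):
        seqs = make_multispecies_family(3, 1, 0, 1.0, 600, seed=4)
        assert len(seqs) == 3
        assert len({s.bases for s in seqs}) == 1
        assert len({s.species for s in seqs}) == 3

    def test_three_species_pairwise_divergence(self):
        seqs = make_multispecies_family(3, 2, 0, 0.96, 900, seed=5)
        fams = {}
        for s in seqs:
            fams.setdefault(s.family_id, []).append(s)
        for members in fams.values():
            for i in range(3):
                for j in range(i + 1, 3):
                    assert hamming(members[i].bases, members[j].bases) == 36


class TestFragmentSequence:
    def test_rounding_convention(self):
        seq = random_seq(16111, seed=6)
        frag = fragment_sequence(seq, 0.4419, anchor="start")
        # 0.4419 * 16111 = 7119.45...: half-up keeps the floor here
        assert len(frag) == round_half_up(0.4419 * 16111) == 7119
        assert seq.bases.startswith(frag.bases)

    def test_full_fraction_flags_fragment(self):
        seq = random_seq(90, seed=2)
        frag = fragment_sequence(seq, 1.0, anchor="start")
        assert frag.bases == seq.bases
        assert frag.is_fragment
        assert frag.parent_interval == (0, 90)

    def test_end_anchor(self):
        seq = random_seq(100, seed=3)
        frag = fragment_sequence(seq, 0.5, anchor="end")
        assert frag.bases == seq.bases[-50:]
        assert frag.parent_interval == (50, 100)

    def test_random_anchor_provenance(self):
        seq = random_seq(200, seed=9)
        frag = fragment_sequence(seq, 0.3, anchor="random", seed=13)
        lo, hi = frag.parent_interval
        assert seq.bases[lo:hi] == frag.bases
        assert frag.parent_id == seq.id

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValueError):
            fragment_sequence(random_seq(100, seed=1), 0.001)


class TestSimulateReadPairs:
    def test_zero_error_reads_are_substrings(self):
        src = random_seq(10000, seed=20, sid="g")
        pairs = simulate_read_pairs([src], 100, 10.0, 0.0, 300, seed=5)
        assert len(pairs) == 500  # coverage * len / (2 * read_length)
        for p in pairs[:50]:
            assert p.read1 in src.bases
            assert reverse_complement(p.read2) in src.bases
            assert p.insert_size >= 100
            frag = src.bases[p.start:p.start + p.insert_size]
            assert frag.startswith(p.read1)
            assert frag.endswith(reverse_complement(p.read2))

    def test_error_rate_within_binomial_ci(self):
        src = random_seq(20000, seed=21, sid="g")
        pairs = simulate_read_pairs([src], 100, 10.0, 0.01, 300, seed=6)
        mismatches = total = 0
        for p in pairs:
            frag = src.bases[p.start:p.start + p.insert_size]
            mismatches += hamming(p.read1, frag[:100])
            mismatches += hamming(p.read2, reverse_complement(frag[-100:]))
            total += 200
        rate = mismatches / total
        half = 2.576 * np.sqrt(0.01 * 0.99 / total)  # 99% CI
        assert abs(rate - 0.01) < half

    def test_empty_sources(self):
        assert simulate_read_pairs([], 100, 10.0, 0.0, 300, seed=1) == []

    def test_short_source_skipped_with_warning(self):
        short = random_seq(150, seed=2, sid="tiny")
        with pytest.warns(UserWarning, match="tiny"):
            pairs = simulate_read_pairs([short], 100, 5.0, 0.0, 300, seed=1)
        assert pairs == []

    def test_reproducibility(self):
        src = random_seq(3000, seed=22, sid="g")
        a = simulate_read_pairs([src], 100, 5.0, 0.01, 300, seed=9)
        b = simulate_read_pairs([src], 100, 5.0, 0.01, 300, seed=9)
        assert [dataclasses.astuple(p) for p in a] == \
               [dataclasses.astuple(p) for p in b]
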