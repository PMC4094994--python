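"""Degree-sequence machinery: realizability checks and samplers."""

import numpy as np
import pytest
import networkx as nx
from hypothesis import given, settings, strategies as st

from modgen import (
    CoarseMultigraphSequence,
    DegreeDistribution,
    FeasibilityError,
    InputError,
    Partition,
    SamplingError,
    chungphaisan_check,
    erdos_gallai_check,
    handshake_check,
    sample_degree_sequence,
    sample_module_sizes,
    sample_within_degree_sequence,
)

from oracles import (
    brute_graphical,
    brute_multigraph_realizable,
    nonincreasing_sequences,
)


class TestModuleSizes:
    @pytest.mark.parametrize(
        "n, k, expect",
        [(150, 3, [50, 50, 50]), (10, 3, [4, 3, 3]), (7, 1, [7])],
    )
    def test_equal_split_with_remainder(self, n, k, expect, rng):
        assert list(sample_module_sizes(n, k, "equal", rng)) == expect

    def test_explicit_sizes_validated(self, rng):
        assert list(sample_module_sizes(10, 2, [4, 6], rng)) == [4, 6]
        with pytest.raises(InputError):
            sample_module_sizes(10, 2, [4, 7], rng)

    def test_distribution_sampled_sizes_sum_to_n(self, rng):
        dist = DegreeDistribution("poisson", mean=20.0)
        sizes = sample_module_sizes(100, 5, dist, rng)
        assert sizes.sum() == 100 and (sizes > 0).all()


class TestHandshake:
    @pytest.mark.parametrize(
        "seq, ok", [((1, 1), True), ((1, 1, 1), False), ((3, 3, 1, 1), True)]
    )
    def test_examples(self, seq, ok):
        assert handshake_check(seq) is ok


class TestErdosGallai:
    @pytest.mark.parametrize(
        "seq, ok",
        [((1, 1), True), ((3, 3, 1, 1), False), ((2, 2, 2), True), ((), True)],
    )
    def test_examples(self, seq, ok):
        assert erdos_gallai_check(seq) is ok

    def test_negative_entries_are_an_error(self):
        with pytest.raises(InputError):
            erdos_gallai_check([2, -1])

    def test_exhaustive_against_enumeration_up_to_five_nodes(self):
        for seq in nonincreasing_sequences(5, 4):
            assert erdos_gallai_check(seq) == brute_graphical(seq), seq

    def test_full_grid_against_networkx(self):
        # all non-increasing sequences of length <= 8 with entries <= 7
        for seq in nonincreasing_sequences(8, 7):
            assert erdos_gallai_check(seq) == nx.is_graphical(list(seq)), seq


class TestChungphaisan:
    def test_examples(self):
        assert chungphaisan_check(CoarseMultigraphSequence((0, 0, 0), b=0))
        assert chungphaisan_check(CoarseMultigraphSequence((4, 4), b=4))
        assert chungphaisan_check(CoarseMultigraphSequence((2, 1, 1), b=1))
        assert not chungphaisan_check(CoarseMultigraphSequence((4, 4), b=3))

    def test_full_grid_against_branch_and_prune(self):
        # length <= 5, entries <= 6, multiplicity cap b <= 3
        for b in range(4):
            for seq in nonincreasing_sequences(5, 6):
                got = chungphaisan_check(CoarseMultigraphSequence(seq, b=b))
                want = brute_multigraph_realizable(seq, b)
                assert got == want, (seq, b)


class TestDegreeSequenceSampling:
    def test_explicit_sequence_passthrough(self, rng):
        seq = [3, 3, 2, 2, 2]
        out = sample_degree_sequence(seq, 5, rng)
        assert list(out) == seq

    def test_explicit_nongraphical_rejected(self, rng):
        with pytest.raises(InputError):
            sample_degree_sequence([3, 3, 1, 1], 4, rng)
        with pytest.raises(InputError):
            sample_degree_sequence([2, 1, 1, 0], 4, rng)

    @pytest.mark.parametrize("family", ["poisson", "geometric", "powerlaw"])
    def test_families_hit_the_mean_without_zeros(self, family, rng):
        # the pure zeta power law with mean 10 has alpha < 2, whose extreme
        # hubs make most i.i.d. draws non-graphical; k_min=2 keeps the same
        # family with a realizable tail
        dist = DegreeDistribution(family, mean=10.0, k_min=2)
        seq = sample_degree_sequence(dist, 2000, rng)
        assert seq.min() >= 1
        assert abs(seq.mean() - 10.0) <= 0.5
        assert seq.sum() % 2 == 0
        assert erdos_gallai_check(seq)

    def test_powerlaw_k_min_raises_the_floor(self, rng):
        dist = DegreeDistribution("powerlaw", mean=5.0, k_min=2)
        seq = sample_degree_sequence(dist, 500, rng)
        assert seq.min() >= 2
        assert abs(seq.mean() - 5.0) <= 0.25

    def test_truncated_poisson_mean_is_corrected(self, rng):
        # with zero-truncation the raw lambda would overshoot the mean
        dist = DegreeDistribution("poisson", mean=2.0)
        draws = dist.sample(20000, rng, k_max=100)
        assert draws.min() >= 1
        assert abs(draws.mean() - 2.0) < 0.05


class TestWithinDegreeSampling:
    def _triples(self, rng, family="poisson", n=200, k=4, d_mean=8.0, dw_mean=5.0):
        dist = DegreeDistribution(family, mean=d_mean)
        D = sample_degree_sequence(dist, n, rng)
        part = Partition.from_sizes([n // k] * k)
        triples = sample_within_degree_sequence(
            D, part, dw_mean, dist.with_mean(dw_mean), 0.01 * d_mean * 10, rng
        )
        return D, part, triples

    def test_identity_and_parity_invariants(self, rng):
        D, part, t = self._triples(rng)
        assert np.array_equal(t.d, t.d_w + t.d_b)
        t.validate_parity(part)
        assert (t.d_w >= 0).all() and (t.d_b >= 0).all()

    def test_within_degrees_respect_module_capacity(self, rng):
        D, part, t = self._triples(rng, k=8, n=160)
        sizes = part.sizes
        for v in range(t.n_nodes):
            s = sizes[part.assignment[v] - 1]
            assert t.d_w[v] <= min(t.d[v], s - 1)

    def test_per_module_sequences_are_graphical(self, rng):
        D, part, t = self._triples(rng)
        for k in range(1, part.n_modules + 1):
            module_w = t.d_w[part.members(k)]
            assert module_w.sum() % 2 == 0
            assert erdos_gallai_check(module_w)

    def test_single_module_all_within(self, rng):
        dist = DegreeDistribution("poisson", mean=6.0)
        D = sample_degree_sequence(dist, 100, rng)
        part = Partition.single(100)
        t = sample_within_degree_sequence(
            D, part, float(D.mean()), dist.with_mean(float(D.mean())), 0.06, rng
        )
        assert np.array_equal(t.d_w, D)
        assert (t.d_b == 0).all()

    def test_small_forced_example(self, rng):
        # degrees (3,2 | 3,2) in two modules of 2: every node must get
        # d_w = 1 (d_w <= s_k - 1 = 1, per-module parity, and the
        # between-multigraph balance rule out every other assignment)
        D = np.array([3, 2, 3, 2])
        part = Partition.from_sizes([2, 2])
        dist = DegreeDistribution("poisson", mean=1.0)
        t = sample_within_degree_sequence(D, part, 1.0, dist, 0.062, rng)
        assert list(t.d_w) == [1, 1, 1, 1]
        assert list(t.d_b) == [2, 1, 2, 1]

    def test_thinning_mode_satisfies_all_conditions(self, rng):
        dist = DegreeDistribution("powerlaw", mean=5.0, k_min=2)
        D = sample_degree_sequence(dist, 150, rng)
        part = Partition.from_sizes([50, 50, 50])
        dw_mean = 0.8 * float(D.mean())
        t = sample_within_degree_sequence(D, part, dw_mean, None, 0.05, rng)
        assert (t.d_w <= t.d).all()
        for k in (1, 2, 3):
            module_w = t.d_w[part.members(k)]
            assert module_w.sum() % 2 == 0
            assert erdos_gallai_check(module_w)

    def test_explicit_within_sequence_validated(self, rng):
        D = np.array([2, 2, 2, 2])
        part = Partition.from_sizes([2, 2])
        t = sample_within_degree_sequence(D, part, 1.0, [1, 1, 1, 1], 0.5, rng)
        assert list(t.d_w) == [1, 1, 1, 1]
        with pytest.raises(InputError):
            sample_within_degree_sequence(D, part, 1.0, [3, 1, 1, 1], 0.5, rng)

    def test_infeasible_mean_raises(self, rng):
        D = np.array([2, 2, 2, 2])
        part = Partition.from_sizes([2, 2])
        with pytest.raises((SamplingError, FeasibilityError)):
            sample_within_degree_sequence(
                D, part, 3.0, DegreeDistribution("poisson", mean=3.0), 0.1, rng
            )
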