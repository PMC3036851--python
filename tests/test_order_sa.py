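import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkorder import (
    DistanceMatrix,
    DomainError,
    MarkerOrder,
    SAConfig,
    anneal,
    anneal_best_of,
    sarf,
)
from linkorder.core import ConfigurationError
from linkorder.order_sa import accept_probability, cooling, neighbor
from linkorder.oracle import exhaustive_best_order

from conftest import random_r_matrix


class TestNeighbor:
    def test_two_markers_sole_neighbor_is_reversal(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert neighbor(MarkerOrder((0, 1)), rng, "swap").perm == (1, 0)
            assert neighbor(MarkerOrder((0, 1)), rng, "reverse").perm == (1, 0)

    def test_swap_position_pairs_uniform(self):
        """Every unordered position pair of k=5 is drawn uniformly."""
        rng = np.random.default_rng(1)
        base = MarkerOrder((0, 1, 2, 3, 4))
        counts = Counter()
        n = 10_000
        for _ in range(n):
            moved = [
                i for i, (a, b) in enumerate(zip(base.perm, neighbor(base, rng, "swap").perm))
                if a != b
            ]
            counts[tuple(moved)] += 1
        n_pairs = 10  # C(5,2)
        p = 1 / n_pairs
        se = math.sqrt(p * (1 - p) * n)
        assert len(counts) == n_pairs
        for pair, c in counts.items():
            assert abs(c - n * p) < 3.5 * se

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(2, 9), st.integers(0, 1000), st.sampled_from(["swap", "reverse"]))
    def test_output_is_valid_permutation_and_differs(self, k, seed, kind):
        rng = np.random.default_rng(seed)
        base = MarkerOrder(tuple(np.random.default_rng(seed + 1).permutation(k)))
        out = neighbor(base, rng, kind)
        assert sorted(out.perm) == list(range(k))
        assert out.perm != base.perm


class TestAcceptProbability:
    def test_non_worsening_always_accepted(self):
        assert accept_probability(10.0, 10.0, 0.5) == 1.0
        assert accept_probability(10.0, 9.0, 0.5) == 1.0

    def test_closed_form_at_delta_equal_c(self):
        assert accept_probability(1.0, 3.0, 2.0) == pytest.approx(math.exp(-1))

    def test_monotone_in_delta_and_temperature(self):
        deltas = np.linspace(0.1, 5, 20)
        probs = [accept_probability(0.0, d, 1.0) for d in deltas]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        cs = np.linspace(0.1, 5, 20)
        probs = [accept_probability(0.0, 1.0, c) for c in cs]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(DomainError):
            accept_probability(1.0, 2.0, 0.0)

    def test_strict_descent_in_cold_limit(self):
        # at c -> 0+ the rule degenerates to strict descent: acceptance of a
        # worsening move underflows to exactly zero
        rng = np.random.default_rng(3)
        deltas = rng.uniform(1e-6, 10, size=10_000)
        assert all(accept_probability(0.0, d, 1e-12) == 0.0 for d in deltas)


class TestCooling:
    @pytest.mark.parametrize("schedule", ["linear", "geometric", "logarithmic"])
    def test_starts_at_A_default_2(self, schedule):
        cfg = SAConfig(schedule=schedule)
        assert cooling(0, cfg) == pytest.approx(2.0)

    def test_linear_end_positive(self):
        cfg = SAConfig(m=100)
        assert cooling(100, cfg) == pytest.approx(2.0 / 101)
        assert cooling(100, cfg) > 0

    @pytest.mark.parametrize("schedule", ["linear", "geometric", "logarithmic"])
    def test_non_increasing_and_positive(self, schedule):
        cfg = SAConfig(m=200, schedule=schedule)
        seq = [cooling(n, cfg) for n in range(201)]
        assert all(c > 0 for c in seq)
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_unknown_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            SAConfig(schedule="exponential-ish")


class TestAnneal:
    def test_two_markers_trivial(self):
        D = DistanceMatrix(d=np.array([[0.0, 4.0], [4.0, 0.0]]))
        res = anneal(D, SAConfig(m=1, L=1, seed=0))
        assert res.order.perm == (0, 1)
        assert res.sarf == pytest.approx(4.0)

    def test_recovers_identity_on_collinear_six_markers(self):
        D = DistanceMatrix.from_positions([0, 20, 40, 60, 80, 100])
        res = anneal(D, SAConfig(m=500, seed=11))
        assert res.order.perm == tuple(range(6))
        oracle_order, oracle_val = exhaustive_best_order(D)
        assert res.sarf == pytest.approx(oracle_val)
        assert res.order.perm == oracle_order.perm

    def test_best_of_20_matches_oracle_on_random_k8(self):
        rng = np.random.default_rng(23)
        D = random_r_matrix(rng, 8)
        _, oracle_val = exhaustive_best_order(D)
        hits = 0
        for seed in range(20):
            res = anneal(D, SAConfig(seed=seed, record_trajectory=False))
            assert res.sarf >= oracle_val - 1e-9
            hits += res.sarf <= oracle_val + 1e-9
        assert hits >= 19

    def test_trajectory_contract(self):
        rng = np.random.default_rng(4)
        D = random_r_matrix(rng, 7)
        res = anneal(D, SAConfig(m=300, seed=5))
        traj = res.trajectory
        best = traj["best_sarf"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)  # best-so-far non-increasing
        assert best[-1] == pytest.approx(res.sarf, abs=1e-9)
        # final SARF equals an independent recomputation on the order
        assert res.sarf == pytest.approx(sarf(res.order, D))
        temps = traj["temperature"].to_numpy()
        assert np.all(np.diff(temps) <= 1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        D = random_r_matrix(rng, 10)
        a = anneal(D, SAConfig(m=400, seed=77))
        b = anneal(D, SAConfig(m=400, seed=77))
        assert a.order.perm == b.order.perm
        assert a.sarf == b.sarf
        assert a.accepted == b.accepted

    def test_recovers_true_order_on_all_benchmark_groups(self, genome):
        """On true-map distance matrices every group's order is recovered."""
        for g in genome.groups:
            D = DistanceMatrix.from_positions(g.positions, names=g.names)
            res = anneal(D, SAConfig(seed=2024, record_trajectory=False))
            assert res.order.perm == tuple(range(g.k)), f"group with k={g.k}"
            assert res.sarf == pytest.approx(100.0)

    def test_swap_neighborhood_also_solves_small_groups(self, genome):
        g = genome.groups[3]
        D = DistanceMatrix.from_positions(g.positions)
        res = anneal(D, SAConfig(seed=1, neighborhood="swap", record_trajectory=False))
        assert res.order.perm == tuple(range(6))

    def test_patience_stops_early(self):
        rng = np.random.default_rng(9)
        D = random_r_matrix(rng, 6)
        res = anneal(D, SAConfig(m=5000, patience=50, seed=3, record_trajectory=False))
        assert res.evaluations < 5000 * 6

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            anneal(DistanceMatrix(d=np.zeros((1, 1))))


class TestAnnealBestOf:
    def test_best_is_min_of_repetitions(self):
        rng = np.random.default_rng(10)
        D = random_r_matrix(rng, 9)
        best, all_runs = anneal_best_of(D, reps=5, config=SAConfig(m=200, record_trajectory=False), seed=1)
        assert best.sarf == pytest.approx(min(r.sarf for r in all_runs))
        # reproducible ensemble
        best2, _ = anneal_best_of(D, reps=5, config=SAConfig(m=200, record_trajectory=False), seed=1)
        assert best2.order.perm == best.order.perm
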