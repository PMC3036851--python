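import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkorder import (
    ConfigurationError,
    DistanceMatrix,
    DomainError,
    MarkerOrder,
    ObjectiveKind,
    SizeMismatchError,
    canonicalize,
    map_function,
    objective,
    sarf,
)
from linkorder.core import path_length_cm
from linkorder.oracle import exhaustive_best_order

from conftest import brute_force_best


def toy_matrix(k, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.uniform(1, 50, size=(k, k))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d)


class TestSarf:
    def test_true_order_of_sparse_group_spans_100_cm(self, group4_true_matrix):
        # 6 markers spaced 20 cM: the identity order walks the full 100 cM map
        assert sarf(MarkerOrder(tuple(range(6))), group4_true_matrix) == pytest.approx(100.0)

    def test_two_markers_is_their_single_interval(self):
        D = DistanceMatrix(d=np.array([[0.0, 7.5], [7.5, 0.0]]))
        assert sarf((0, 1), D) == pytest.approx(7.5)
        assert sarf((1, 0), D) == pytest.approx(7.5)

    def test_matches_hand_summed_cells_on_toy_matrix(self):
        D = toy_matrix(4, seed=3)
        order = (2, 0, 1, 3)
        expected = D.d[2, 0] + D.d[0, 1] + D.d[1, 3]
        assert sarf(order, D) == pytest.approx(expected)
        # cross-check against the independent full-enumeration oracle
        perm, val = brute_force_best(D.d)
        all_vals = {
            p: sum(D.d[p[i], p[i + 1]] for i in range(3))
            for p in itertools.permutations(range(4))
        }
        assert sarf(order, D) == pytest.approx(all_vals[order])
        assert val == pytest.approx(min(all_vals.values()))

    def test_reversal_invariance(self):
        D = toy_matrix(7, seed=5)
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = tuple(rng.permutation(7))
            assert sarf(p, D) == pytest.approx(sarf(tuple(reversed(p)), D))

    def test_size_and_domain_errors(self):
        D = toy_matrix(4)
        with pytest.raises(SizeMismatchError):
            sarf((0, 1, 2), D)
        with pytest.raises(DomainError):
            sarf((0,), DistanceMatrix(d=np.zeros((1, 1))))

    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_identity_minimises_sarf_on_collinear_matrices(self, k):
        positions = np.cumsum(np.random.default_rng(k).uniform(1, 15, size=k))
        D = DistanceMatrix.from_positions(positions)
        order, val = exhaustive_best_order(D)
        assert order.perm == tuple(range(k))
        assert val == pytest.approx(sarf(tuple(range(k)), D))


class TestObjective:
    def test_sarf_kind_equals_sarf_function(self):
        D = toy_matrix(5, seed=9)
        for p in [(0, 1, 2, 3, 4), (3, 1, 4, 0, 2)]:
            assert objective(p, D, ObjectiveKind.SARF) == pytest.approx(sarf(p, D))
            assert objective(p, D, "sarf") == pytest.approx(sarf(p, D))

    def test_parf_zero_factor_and_salod_single_interval(self):
        r = np.array([[0.0, 0.0, 0.2], [0.0, 0.0, 0.3], [0.2, 0.3, 0.0]])
        lod = np.array([[0.0, 5.0], [5.0, 0.0]])
        D = DistanceMatrix(d=np.where(r > 0, 30.0, 0.0), r=r)
        assert objective((0, 1, 2), D, ObjectiveKind.PARF) == 0.0
        D2 = DistanceMatrix(d=np.array([[0.0, 10.0], [10.0, 0.0]]), lod=lod)
        assert objective((0, 1), D2, ObjectiveKind.SALOD) == pytest.approx(5.0)

    def test_missing_companion_matrix_is_configuration_error(self):
        D = toy_matrix(3)
        with pytest.raises(ConfigurationError):
            objective((0, 1, 2), D, ObjectiveKind.PARF)
        with pytest.raises(ConfigurationError):
            objective((0, 1, 2), D, ObjectiveKind.SALOD)


class TestMapFunction:
    def test_zero_distance_maps_to_zero(self):
        assert map_function(0.0, "cm_to_r", "haldane") == 0.0
        assert map_function(0.0, "cm_to_r", "kosambi") == 0.0

    def test_haldane_closed_form_at_2_cm(self):
        expected = (1.0 - math.exp(-0.04)) / 2.0
        assert map_function(2.0, "cm_to_r", "haldane") == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kind", ["haldane", "kosambi"])
    def test_round_trip_identity(self, kind):
        for d in np.linspace(0.0, 49.9, 25):
            r = map_function(d, "cm_to_r", kind)
            assert map_function(r, "r_to_cm", kind) == pytest.approx(d, abs=1e-10)

    def test_unlinked_r_maps_to_cap_not_error(self):
        assert map_function(0.5, "r_to_cm", "haldane") == 100.0
        assert map_function(0.5, "r_to_cm", "haldane", cap=75.0) == 75.0
        assert map_function(0.4999, "r_to_cm", "haldane") == 100.0  # capped

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            map_function(-1.0, "cm_to_r", "haldane")
        with pytest.raises(ConfigurationError):
            map_function(1.0, "cm_to_r", "morgan")


class TestCanonicalize:
    def test_reversal_rule(self):
        assert canonicalize((3, 1, 0, 2)).perm == (2, 0, 1, 3)
        assert canonicalize((0, 1, 2)).perm == (0, 1, 2)

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_canonical_of_reverse_is_canonical_of_order(self, perm):
        perm = tuple(perm)
        assert canonicalize(tuple(reversed(perm))).perm == canonicalize(perm).perm
        # idempotence
        assert canonicalize(canonicalize(perm)).perm == canonicalize(perm).perm

    def test_invalid_permutation_rejected(self):
        with pytest.raises(DomainError):
            MarkerOrder((0, 0, 1))


class TestDistanceMatrix:
    def test_asymmetric_and_nonfinite_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(Exception):
            DistanceMatrix(d=bad)
        with pytest.raises(Exception):
            DistanceMatrix(d=np.array([[0.0, np.inf], [np.inf, 0.0]]))

    def test_from_positions_matches_pairwise_gaps(self):
        D = DistanceMatrix.from_positions([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
        assert D.d[0, 5] == pytest.approx(100.0)
        assert D.d[1, 3] == pytest.approx(40.0)
        assert D.r[0, 1] == pytest.approx((1 - math.exp(-0.4)) / 2)

    def test_path_length_cm_reads_cm_matrix_regardless_of_units(self):
        r = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.1], [0.2, 0.1, 0.0]])
        d = np.array([[0.0, 11.0, 26.0], [11.0, 0.0, 11.0], [26.0, 11.0, 0.0]])
        D = DistanceMatrix(d=d, r=r, units="r")
        assert sarf((0, 1, 2), D) == pytest.approx(0.2)
        assert path_length_cm((0, 1, 2), D) == pytest.approx(22.0)
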