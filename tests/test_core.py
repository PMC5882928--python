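"""Distance, proximity and discrimination-value behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcs import (
    LabeledPointSet,
    discrimination_value,
    global_discrimination,
    pairwise_distances,
    proximity_matrix,
    proximity_of,
)
from mcs.errors import (
    DegenerateClusterError,
    InvalidInputError,
    InvalidPairError,
)

from conftest import brute_force_global_delta, brute_force_proximity


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)
        assert d.values[1, 0] == pytest.approx(5.0)
        assert np.all(np.diag(d.values) == 0)

    def test_duplicated_points_give_zero_matrix(self):
        d = pairwise_distances(np.ones((4, 3)))
        assert np.all(d.values == 0)

    def test_rectangle_cross_distances(self, rectangle_points):
        d = pairwise_distances(rectangle_points).values
        cross = sorted([d[0, 2], d[0, 3], d[1, 2], d[1, 3]])
        assert cross == pytest.approx([10.0, 10.0, np.sqrt(104), np.sqrt(104)])

    def test_non_finite_coordinate_names_row(self):
        coords = np.zeros((3, 2))
        coords[1, 0] = np.nan
        with pytest.raises(InvalidInputError, match=r"\[1\]"):
            pairwise_distances(coords)


class TestProximityMatrix:
    def test_rectangle_block_means(self, rectangle_points):
        prox = proximity_of(rectangle_points)
        assert prox.proximity("A", "A") == pytest.approx(2.0)
        assert prox.proximity("B", "B") == pytest.approx(2.0)
        expected = (10 + np.sqrt(104) + np.sqrt(104) + 10) / 4
        assert prox.proximity("A", "B") == pytest.approx(expected)
        assert prox.proximity("A", "B") == prox.proximity("B", "A")

    def test_identical_overlapping_clusters(self):
        pts = LabeledPointSet(
            np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 0.0], [0.0, 2.0]]),
            ["A", "A", "B", "B"])
        prox = proximity_of(pts)
        assert prox.proximity("A", "A") == pytest.approx(2.0)
        assert prox.proximity("A", "B") == pytest.approx((0 + 2 + 2 + 0) / 4)

    def test_all_identical_points_zero_proximities(self):
        pts = LabeledPointSet(np.zeros((6, 3)), ["A"] * 3 + ["B"] * 3)
        assert np.all(proximity_of(pts).values == 0)

    def test_singleton_cluster_rejected(self):
        d = pairwise_distances(np.arange(6.0).reshape(3, 2))
        with pytest.raises(DegenerateClusterError):
            proximity_matrix(d, ["A", "A", "B"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 4), st.integers(1, 5))
    def test_matches_brute_force_double_loop(self, seed, n_labels, dim):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 8, size=n_labels)
        order = tuple("ABCD"[:n_labels])
        labels = np.repeat(np.array(order, dtype=object), sizes)
        rng.shuffle(labels)
        coords = rng.normal(size=(labels.size, dim))
        prox = proximity_matrix(pairwise_distances(coords), labels, order)
        oracle = brute_force_proximity(coords, labels, order)
        np.testing.assert_allclose(prox.values, oracle, atol=1e-10)
        # symmetry and nonnegativity ride along
        np.testing.assert_allclose(prox.values, prox.values.T, atol=1e-12)
        assert np.all(prox.values >= 0)


class TestDiscriminationValue:
    def test_disjoint_clusters_negative(self, rectangle_points):
        prox = proximity_of(rectangle_points)
        delta = discrimination_value(prox, "A", "B")
        assert delta == pytest.approx(2 + 2 - 2 * 10.09901951359278, abs=1e-9)
        assert delta < 0
        assert discrimination_value(prox, "B", "A") == delta

    def test_overlapping_clusters_positive(self):
        pts = LabeledPointSet(
            np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 0.0], [0.0, 2.0]]),
            ["A", "A", "B", "B"])
        assert discrimination_value(proximity_of(pts), "A", "B") == pytest.approx(2.0)

    def test_identical_points_zero_boundary(self):
        pts = LabeledPointSet(np.zeros((6, 2)), ["A"] * 3 + ["B"] * 3)
        assert discrimination_value(proximity_of(pts), "A", "B") == 0.0

    def test_same_label_pair_rejected(self, rectangle_points):
        with pytest.raises(InvalidPairError):
            discrimination_value(proximity_of(rectangle_points), "A", "A")

    def test_rigid_motion_invariance(self, rectangle_points):
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        moved = LabeledPointSet(
            rectangle_points.coordinates @ q.T + np.array([5.0, -3.0]),
            rectangle_points.labels, rectangle_points.label_order)
        d0 = discrimination_value(proximity_of(rectangle_points), "A", "B")
        d1 = discrimination_value(proximity_of(moved), "A", "B")
        assert d1 == pytest.approx(d0, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scaling_linearity(self, scale):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(12, 3))
        labels = ["A"] * 6 + ["B"] * 6
        d0 = discrimination_value(
            proximity_of(LabeledPointSet(coords, labels)), "A", "B")
        d1 = discrimination_value(
            proximity_of(LabeledPointSet(coords * scale, labels)), "A", "B")
        assert d1 == pytest.approx(scale * d0, rel=1e-9)

    def test_moving_clusters_apart_decreases_delta(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 4))
        labels = ["A"] * 10 + ["B"] * 10
        deltas = []
        for shift in [0.0, 1.0, 3.0, 8.0]:
            coords = base.copy()
            coords[10:, 0] += shift
            deltas.append(discrimination_value(
                proximity_of(LabeledPointSet(coords, labels)), "A", "B"))
        assert all(b < a for a, b in zip(deltas, deltas[1:]))


class TestGlobalDiscrimination:
    def test_two_labels_reduce_to_pairwise(self, rectangle_points):
        prox = proximity_of(rectangle_points)
        assert global_discrimination(prox) == pytest.approx(
            discrimination_value(prox, "A", "B"))

    def test_three_identical_clusters_zero(self):
        pts = LabeledPointSet(np.zeros((6, 2)), ["A", "A", "B", "B", "C", "C"])
        assert global_discrimination(proximity_of(pts)) == 0.0

    def test_three_clusters_sum_of_pairwise(self):
        coords = np.array([[0, 0], [0, 2], [10, 0], [10, 2], [0, 100], [0, 102]],
                          dtype=float)
        labels = ["A", "A", "B", "B", "C", "C"]
        pts = LabeledPointSet(coords, labels)
        prox = proximity_of(pts)
        expected = sum(discrimination_value(prox, a, b)
                       for a, b in [("A", "B"), ("A", "C"), ("B", "C")])
        assert global_discrimination(prox) == pytest.approx(expected)
        oracle = brute_force_global_delta(coords, labels, ("A", "B", "C"))
        assert global_discrimination(prox) == pytest.approx(oracle)


class TestLabeledPointSet:
    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidInputError):
            LabeledPointSet(np.zeros((2, 2)), ["A", "B"], label_order=("A",))

    def test_subset_keeps_time_metadata(self, line_points):
        pts = LabeledPointSet(line_points.coordinates, line_points.labels,
                              time=np.arange(4.0))
        sub = pts.subset(["B"])
        assert sub.n_points == 2
        np.testing.assert_array_equal(sub.time, [2.0, 3.0])
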