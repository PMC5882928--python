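"""Permutation-null machinery: shuffles, p-value estimators, calibration."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from mcs import (
    LabeledPointSet,
    PermutationConfig,
    make_gaussian_clusters,
    n_distinct_labelings,
    pairwise_pvalue_matrix,
    permutation_test_global,
    permutation_test_pair,
    permute_labels,
)
from mcs.synthetic import ClusterSpec
from mcs.errors import DegenerateClusterError, InvalidConfigError

from conftest import brute_force_global_delta


def exhaustive_pair_pvalues(points, a, b):
    """Independent oracle: enumerate every count-preserving labeling with
    itertools and compute the null with the brute-force delta."""
    sub = points.subset([a, b])
    n_a = int(np.sum(sub.labels == a))
    deltas = []
    for pos in itertools.combinations(range(sub.n_points), n_a):
        labels = np.array([b] * sub.n_points, dtype=object)
        labels[list(pos)] = a
        deltas.append(brute_force_global_delta(sub.coordinates, labels, (a, b)))
    deltas = np.array(deltas)
    d0 = brute_force_global_delta(sub.coordinates, sub.labels, (a, b))
    return (d0, np.mean(deltas < d0), np.mean(deltas <= d0))


class TestPermuteLabels:
    def test_full_shuffle_is_uniform_over_arrangements(self):
        # AABB has 6 distinct count-preserving arrangements
        rng = np.random.default_rng(123)
        counts = {}
        for _ in range(60_000):
            arr = "".join(permute_labels(list("AABB"), rng=rng))
            counts[arr] = counts.get(arr, 0) + 1
        assert len(counts) == 6
        stat = chisquare(list(counts.values()))
        assert stat.pvalue > 1e-4

    def test_singleton_unchanged(self):
        out = permute_labels(["A"], rng=np.random.default_rng(0))
        assert list(out) == ["A"]

    def test_block_shuffle_preserves_multiset(self):
        labels = list("AABBBCC")
        rng = np.random.default_rng(7)
        for bl in (1, 2, 3, 7):
            out = permute_labels(labels, scheme="block_shuffle", rng=rng,
                                 block_length=bl)
            assert sorted(out) == sorted(labels)

    def test_block_length_of_m_is_identity(self):
        labels = list("AABB")
        out = permute_labels(labels, scheme="block_shuffle",
                             rng=np.random.default_rng(0), block_length=4)
        assert list(out) == labels

    def test_block_length_exceeding_m_rejected(self):
        with pytest.raises(InvalidConfigError):
            permute_labels(list("AABB"), scheme="block_shuffle",
                           rng=np.random.default_rng(0), block_length=5)


class TestExhaustiveBranch:
    def test_line_example_null_distribution(self, line_points):
        res = permutation_test_pair(line_points, "A", "B")
        assert res.exhaustive
        assert res.delta_observed == pytest.approx(-18.0)
        assert sorted(res.delta_null) == pytest.approx([-18, -18, 9, 9, 9, 9])
        assert res.p_value == pytest.approx(2 / 6)

    def test_line_example_strict_mode(self, line_points):
        cfg = PermutationConfig(comparison_mode="paper_literal_strict")
        res = permutation_test_pair(line_points, "A", "B", cfg)
        assert res.p_value == 0.0

    def test_labeling_count(self):
        assert n_distinct_labelings([2, 2]) == 6
        assert n_distinct_labelings([3, 3, 2]) == 560

    def test_matches_independent_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        pts = LabeledPointSet(rng.normal(size=(8, 3)),
                              ["A"] * 4 + ["B"] * 4)
        d0, p_strict, p_leq = exhaustive_pair_pvalues(pts, "A", "B")
        res = permutation_test_pair(pts, "A", "B",
                                    PermutationConfig(exhaustive="always"))
        assert res.delta_observed == pytest.approx(d0)
        assert res.p_value == pytest.approx(p_leq)
        strict = permutation_test_pair(
            pts, "A", "B", PermutationConfig(
                exhaustive="always", comparison_mode="paper_literal_strict"))
        assert strict.p_value == pytest.approx(p_strict)


class TestMonteCarlo:
    def test_fixed_seed_bit_identical(self, rectangle_points):
        cfg = PermutationConfig(n_permutations=500, seed=9, exhaustive="never")
        r1 = permutation_test_pair(rectangle_points, "A", "B", cfg)
        r2 = permutation_test_pair(rectangle_points, "A", "B", cfg)
        np.testing.assert_array_equal(r1.delta_null, r2.delta_null)
        assert r1.p_value == r2.p_value
        assert r1.n_permutations == 500

    def test_null_invariant_to_class_relabeling(self, rectangle_points):
        cfg = PermutationConfig(n_permutations=300, seed=4, exhaustive="never")
        swapped = LabeledPointSet(
            rectangle_points.coordinates,
            np.where(rectangle_points.labels == "A", "B", "A"),
            ("A", "B"))
        r1 = permutation_test_pair(rectangle_points, "A", "B", cfg)
        r2 = permutation_test_pair(swapped, "A", "B", cfg)
        np.testing.assert_allclose(r1.delta_null, r2.delta_null, atol=1e-12)

    def test_add_one_lower_bound(self):
        pts = LabeledPointSet(np.zeros((6, 2)), ["A"] * 3 + ["B"] * 3)
        cfg = PermutationConfig(n_permutations=200, seed=1, exhaustive="never")
        res = permutation_test_pair(pts, "A", "B", cfg)
        # all deltas equal zero -> p = 1 under add-one
        assert res.p_value == 1.0
        assert res.p_value >= 1.0 / (cfg.n_permutations + 1)

    def test_global_equals_pair_for_two_labels(self, rectangle_points):
        cfg = PermutationConfig(n_permutations=400, seed=2, exhaustive="never")
        rp = permutation_test_pair(rectangle_points, "A", "B", cfg)
        rg = permutation_test_global(rectangle_points, cfg)
        np.testing.assert_array_equal(rp.delta_null, rg.delta_null)
        assert rp.p_value == rg.p_value

    def test_degenerate_cluster_rejected(self):
        pts = LabeledPointSet(np.arange(6.0).reshape(3, 2), ["A", "A", "B"])
        with pytest.raises(DegenerateClusterError):
            permutation_test_pair(pts, "A", "B")

    def test_block_shuffle_runs_and_preserves_counts(self):
        spec = ClusterSpec(n_clusters=2, points_per_cluster=12, dimension=4,
                           separation=0.0, seed=0)
        pts = make_gaussian_clusters(spec)
        cfg = PermutationConfig(n_permutations=100, seed=0,
                                scheme="block_shuffle", block_length=4,
                                exhaustive="never")
        res = permutation_test_global(pts, cfg)
        assert 0 <= res.p_value <= 1
        assert res.n_permutations == 100


class TestCalibrationAndPower:
    def _null_rejection_rate(self, alpha, n_rep=200):
        hits = 0
        for i in range(n_rep):
            spec = ClusterSpec(n_clusters=2, points_per_cluster=15,
                               dimension=4, separation=0.0, seed=10_000 + i)
            pts = make_gaussian_clusters(spec)
            cfg = PermutationConfig(n_permutations=199, seed=i,
                                    exhaustive="never")
            if permutation_test_global(pts, cfg).p_value <= alpha:
                hits += 1
        return hits / n_rep

    def test_null_pvalues_near_uniform(self):
        """Exchangeable clusters: rejection rate tracks nominal level."""
        assert 0.015 <= self._null_rejection_rate(0.05) <= 0.10
        assert 0.17 <= self._null_rejection_rate(0.25) <= 0.34

    def test_power_monotone_in_separation(self):
        rates = []
        for sep in (0.0, 1.0, 2.0, 5.0):
            hits = 0
            for i in range(60):
                spec = ClusterSpec(n_clusters=2, points_per_cluster=15,
                                   dimension=16, separation=sep,
                                   seed=20_000 + i)
                cfg = PermutationConfig(n_permutations=199, seed=i,
                                        exhaustive="never")
                res = permutation_test_global(make_gaussian_clusters(spec), cfg)
                hits += res.p_value <= 0.05
            rates.append(hits / 60)
        assert all(b >= a - 0.08 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0] + 0.5

    def test_three_null_clusters_calibrated(self):
        hits = 0
        for i in range(150):
            spec = ClusterSpec(n_clusters=3, points_per_cluster=12,
                               dimension=8, separation=0.0, seed=30_000 + i)
            cfg = PermutationConfig(n_permutations=199, seed=i,
                                    exhaustive="never")
            hits += permutation_test_global(
                make_gaussian_clusters(spec), cfg).p_value <= 0.05
        assert 0.01 <= hits / 150 <= 0.11


class TestPairwiseMatrix:
    def test_separated_clusters_all_significant(self):
        spec = ClusterSpec(n_clusters=4, points_per_cluster=60, dimension=16,
                           separation=5.0, seed=1)
        pts = make_gaussian_clusters(spec)
        cfg = PermutationConfig(n_permutations=1999, seed=1, exhaustive="never")
        mat = pairwise_pvalue_matrix(pts, cfg)
        off = mat.values[~np.eye(4, dtype=bool)]
        assert np.all(off <= 0.001)
        np.testing.assert_array_equal(mat.values, mat.values.T)
        assert np.all(np.isnan(np.diag(mat.values)))

    def test_reproducible_under_fixed_seed(self):
        spec = ClusterSpec(n_clusters=3, points_per_cluster=10, dimension=4,
                           separation=1.0, seed=2)
        pts = make_gaussian_clusters(spec)
        cfg = PermutationConfig(n_permutations=200, seed=5, exhaustive="never")
        m1 = pairwise_pvalue_matrix(pts, cfg)
        m2 = pairwise_pvalue_matrix(pts, cfg)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_holm_correction_never_smaller(self):
        spec = ClusterSpec(n_clusters=3, points_per_cluster=10, dimension=4,
                           separation=1.0, seed=3)
        pts = make_gaussian_clusters(spec)
        cfg = PermutationConfig(n_permutations=200, seed=5, exhaustive="never")
        raw = pairwise_pvalue_matrix(pts, cfg)
        adj = pairwise_pvalue_matrix(pts, cfg, correction="holm")
        mask = ~np.eye(3, dtype=bool)
        assert np.all(adj.values[mask] >= raw.values[mask] - 1e-12)
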