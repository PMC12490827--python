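from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpcharter as fp
from conftest import brute_force_pam_cost


def dist_from_points(points):
    points = np.asarray(points, dtype=float)
    return np.abs(points[:, None] - points[None, :])


def feature_matrix(values, region_width=100):
    """Wrap a dense feature array in a SmoothedMatrix with everything in-window."""
    values = np.asarray(values, dtype=float)
    region = fp.GenomicInterval("chr1", 0, region_width)
    positions = np.arange(1, values.shape[1] + 1)
    return fp.SmoothedMatrix(region, positions, [f"m{i}" for i in range(len(values))], values)


class TestPairwiseDistances:
    def test_identical_rows_have_zero_distance(self):
        d = fp.pairwise_distances(feature_matrix([[0, 0, 1], [0, 0, 1]]))
        assert d[0, 1] == 0.0

    def test_full_rows_reduce_to_euclidean(self):
        d = fp.pairwise_distances(feature_matrix([[0, 0, 1], [1, 0, 1]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_missing_rescaled_formula(self):
        nan = np.nan
        d = fp.pairwise_distances(feature_matrix([[1, nan, 0], [0, nan, 0]]))
        # shared S = {pos1, pos3}, P = 3: sqrt((3/2) * 1)
        assert d[0, 1] == pytest.approx(np.sqrt(1.5))

    def test_disjoint_coverage_gets_max_plus_one(self):
        nan = np.nan
        X = [[1, 1, nan, nan], [nan, nan, 0, 0], [1, 0, 1, 0]]
        d = fp.pairwise_distances(feature_matrix(X))
        finite_max = max(d[0, 2], d[1, 2])
        assert d[0, 1] == pytest.approx(finite_max + 1.0)

    def test_metric_axioms_on_full_coverage(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 8))
        d = fp.pairwise_distances(feature_matrix(X))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d[~np.eye(12, dtype=bool)] >= 0).all()
        for i, j, k in combinations(range(12), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_only_in_window_positions_are_features(self):
        region = fp.GenomicInterval("chr1", 0, 10)
        positions = np.array([5, 8, 50])  # 50 is outside the window
        vals = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        sm = fp.SmoothedMatrix(region, positions, ["a", "b"], vals)
        assert fp.pairwise_distances(sm)[0, 1] == 0.0


class TestPam:
    def test_k_equals_n_gives_zero_cost(self):
        d = dist_from_points([0, 1, 10, 11])
        res = fp.pam(d, 4)
        assert res.total_cost == 0.0
        assert sorted(res.medoids) == [0, 1, 2, 3]

    def test_two_clusters_on_line_match_exhaustive_optimum(self):
        d = dist_from_points([0, 1, 10, 11])
        res = fp.pam(d, 2)
        assert res.total_cost == pytest.approx(2.0)
        assert res.total_cost == pytest.approx(brute_force_pam_cost(d, 2))
        groups = {tuple(np.flatnonzero(res.assignments == c)) for c in (1, 2)}
        assert groups == {(0, 1), (2, 3)}

    def test_k1_medoid_minimizes_total_distance(self):
        rng = np.random.default_rng(1)
        d = dist_from_points(rng.random(9) * 100)
        res = fp.pam(d, 1)
        assert res.total_cost == pytest.approx(d.sum(axis=0).min())

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fp.pam(dist_from_points([0, 1]), 3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n=st.integers(4, 10),
        k=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    def test_build_swap_matches_brute_force_on_tiny_instances(self, n, k, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = fp.pam(d, k)
        optimum = brute_force_pam_cost(d, k)
        assert res.total_cost <= 1.05 * optimum + 1e-12

    def test_local_optimality_no_improving_swap(self):
        rng = np.random.default_rng(3)
        pts = rng.random((30, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = fp.pam(d, 4)
        medoids = list(res.medoids)
        for mi in range(len(medoids)):
            for h in range(30):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                trial_cost = d[:, trial].min(axis=1).sum()
                assert trial_cost >= res.total_cost - 1e-9

    def test_determinism(self):
        rng = np.random.default_rng(5)
        d = dist_from_points(rng.random(25))
        a = fp.pam(d, 5)
        b = fp.pam(d, 5)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.medoids, b.medoids)


class TestSizeFloor:
    def test_outlier_pattern_forces_k_reduction(self):
        # 12 molecules at 0, 3 at 100: pam(2) isolates the 3 -> floor 5 collapses to k=1
        d = dist_from_points([0.0] * 12 + [100.0] * 3)
        res = fp.cluster_with_size_floor(d, k_init=2, min_cluster_size=5)
        assert res.k_final == 1
        assert res.cluster_sizes.tolist() == [15]

    def test_balanced_separable_patterns_keep_k(self):
        d = dist_from_points([0.0] * 10 + [100.0] * 10)
        res = fp.cluster_with_size_floor(d, k_init=2, min_cluster_size=5)
        assert res.k_final == 2
        assert sorted(res.cluster_sizes.tolist()) == [10, 10]

    def test_k_init_one_stays_one(self):
        d = dist_from_points([0, 5, 50])
        assert fp.cluster_with_size_floor(d, k_init=1, min_cluster_size=1).k_final == 1

    def test_too_few_molecules_flagged_low_coverage(self):
        d = dist_from_points([0, 1, 2])
        res = fp.cluster_with_size_floor(d, k_init=16, min_cluster_size=5)
        assert res.k_final == 1 and res.low_coverage

    def test_floor_monotonicity_in_min_cluster_size(self):
        rng = np.random.default_rng(11)
        d = dist_from_points(np.concatenate([rng.random(8), rng.random(8) + 50, rng.random(3) + 200]))
        finals = [
            fp.cluster_with_size_floor(d, k_init=6, min_cluster_size=s).k_final
            for s in (1, 2, 3, 5, 8)
        ]
        assert finals == sorted(finals, reverse=True)

    def test_result_invariants(self):
        rng = np.random.default_rng(13)
        d = dist_from_points(rng.random(40) * 10)
        res = fp.cluster_with_size_floor(d, k_init=8, min_cluster_size=5)
        assert res.cluster_sizes.sum() == 40
        assert res.k_final == 1 or (res.cluster_sizes >= 5).all()
        for cid, m in enumerate(res.medoids, start=1):
            assert res.assignments[m] == cid
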