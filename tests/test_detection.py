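import numpy as np
import pytest

import fpcharter as fp


def single_cluster(n):
    return fp.ClusterResult(
        assignments=np.ones(n, dtype=int), medoids=np.array([0]), k_requested=1, k_final=1
    )


def matrix_from_protection(prot, positions=None, region_end=1000):
    prot = np.asarray(prot, dtype=float)
    if positions is None:
        positions = np.arange(1, prot.shape[1] + 1)
    region = fp.GenomicInterval("chr1", 0, region_end)
    return fp.RegionMatrix(region, positions, [f"m{i}" for i in range(len(prot))], prot)


class TestClusterProfile:
    def test_mean_of_raw_binary_values(self):
        prot = np.vstack([np.ones((6, 3)), np.zeros((4, 3))])
        mat = matrix_from_protection(prot)
        prof = fp.cluster_profile(mat, single_cluster(10), 1)
        assert np.allclose(prof.mean_protection, 0.6)

    def test_low_coverage_positions_dropped(self):
        prot = np.ones((10, 2))
        prot[2:, 1] = np.nan  # covered by only 2 of 10
        mat = matrix_from_protection(prot)
        prof = fp.cluster_profile(mat, single_cluster(10), 1)
        assert prof.positions.tolist() == [1]

    def test_half_coverage_position_kept(self):
        prot = np.ones((10, 2))
        prot[5:, 1] = np.nan  # second position: exactly 50% coverage
        mat = matrix_from_protection(prot)
        prof = fp.cluster_profile(mat, single_cluster(10), 1)
        assert prof.positions.tolist() == [1, 2]


class TestThreshold:
    def make_profile(self, mean):
        return fp.ClusterProfile(1, np.array([10]), np.array([mean]), 10)

    @pytest.mark.parametrize(
        "mean,expected", [(0.51, True), (0.50, False), (0.0, False), (1.0, True)]
    )
    def test_strictly_above_half(self, mean, expected):
        assert fp.call_footprinted_positions(self.make_profile(mean))[0] == expected

    def test_raising_threshold_never_enlarges_stretches(self):
        rng = np.random.default_rng(2)
        prof = fp.ClusterProfile(1, np.arange(30), rng.random(30), 10)
        lo = fp.call_footprinted_positions(prof, 0.3)
        hi = fp.call_footprinted_positions(prof, 0.7)
        assert not (hi & ~lo).any()


class TestSegmentation:
    def positions(self, pat):
        return fp.ClusterProfile(1, np.array([10, 20, 30, 40])[: len(pat)], None, 5)

    def test_interior_run_extracted_without_edge_flags(self):
        prof = fp.ClusterProfile(1, np.array([10, 20, 30, 40]), None, 5)
        runs = fp.segment_stretches(prof, np.array([False, True, True, False]))
        assert runs == [(20, 30, (False, False))]

    def test_run_touching_profile_start_sets_left_flag(self):
        prof = fp.ClusterProfile(1, np.array([10, 20, 30]), None, 5)
        runs = fp.segment_stretches(prof, np.array([True, True, False]))
        assert runs == [(10, 20, (True, False))]

    def test_all_accessible_yields_nothing(self):
        prof = fp.ClusterProfile(1, np.array([10, 20, 30]), None, 5)
        assert fp.segment_stretches(prof, np.zeros(3, bool)) == []

    def test_genomic_gaps_do_not_break_runs(self):
        prof = fp.ClusterProfile(1, np.array([10, 20, 300, 310, 500]), None, 5)
        runs = fp.segment_stretches(prof, np.array([False, True, True, True, False]))
        assert runs == [(20, 310, (False, False))]

    def test_runs_disjoint_and_separated(self):
        rng = np.random.default_rng(4)
        prof = fp.ClusterProfile(1, np.arange(1, 101), None, 5)
        mask = rng.random(100) > 0.5
        runs = fp.segment_stretches(prof, mask)
        for (s1, e1, _), (s2, e2, _) in zip(runs, runs[1:]):
            assert s2 > e1 + 1  # at least one accessible cytosine between runs


class TestClassification:
    @pytest.mark.parametrize(
        "width,expected",
        [(1, "noise"), (4, "noise"), (5, "TF"), (75, "TF"), (76, "unclassified"),
         (120, "unclassified"), (121, "nucleosome"), (200, "nucleosome")],
    )
    def test_width_boundaries(self, width, expected):
        assert fp.classify_footprint(100, 100 + width - 1, (False, False)) == expected

    @pytest.mark.parametrize("edges", [(True, False), (False, True), (True, True)])
    def test_edge_overrides_width(self, edges):
        assert fp.classify_footprint(100, 299, edges) == "unrecognized"
        assert fp.classify_footprint(100, 104, edges) == "unrecognized"

    def test_label_total_over_width_range(self):
        # the label function partitions widths 1..200 into the four classes
        labels = [fp.classify_footprint(1, w, (False, False)) for w in range(1, 201)]
        assert labels.count("noise") == 4
        assert labels.count("TF") == 71
        assert labels.count("unclassified") == 45
        assert labels.count("nucleosome") == 80


class TestDetectAll:
    def test_all_accessible_cluster_detects_nothing(self):
        mat = matrix_from_protection(np.zeros((6, 20)))
        assert fp.detect_all(mat, single_cluster(6)) == []

    def test_detection_ignores_smoothing_window(self, separable_matrix):
        mat, _ = separable_matrix
        sm40 = fp.smooth_matrix(mat, 40)
        sm80 = fp.smooth_matrix(mat, 80)
        c40 = fp.cluster_with_size_floor(fp.pairwise_distances(sm40), 2, 5)
        c80 = fp.cluster_with_size_floor(fp.pairwise_distances(sm80), 2, 5)
        # same partition on separable data; detection consumes raw values only
        assert np.array_equal(np.sort(c40.cluster_sizes), np.sort(c80.cluster_sizes))
        f40 = {(f.start_pos, f.end_pos, f.label) for f in fp.detect_all(mat, c40)}
        f80 = {(f.start_pos, f.end_pos, f.label) for f in fp.detect_all(mat, c80)}
        assert f40 == f80

    def test_molecules_ending_mid_footprint_flag_unrecognized(self):
        # protection continues to the last covered cytosine: no right flank
        prot = np.hstack([np.zeros((8, 5)), np.ones((8, 10))])
        mat = matrix_from_protection(prot)
        fps = fp.detect_all(mat, single_cluster(8))
        assert [f.label for f in fps] == ["unrecognized"]

    def test_two_clusters_yield_one_footprint_each(self):
        prot = np.zeros((12, 40))
        prot[:6, 10:20] = 1.0  # cluster 1: 10 bp stretch
        prot[6:, 25:35] = 1.0  # cluster 2
        clusters = fp.ClusterResult(
            assignments=np.array([1] * 6 + [2] * 6),
            medoids=np.array([0, 6]),
            k_requested=2,
            k_final=2,
        )
        fps = fp.detect_all(matrix_from_protection(prot), clusters)
        assert [(f.cluster_id, f.label, f.width) for f in fps] == [
            (1, "TF", 10),
            (2, "TF", 10),
        ]
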