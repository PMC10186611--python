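import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from subtelo.chromatin import (
    ChromatinError,
    cluster_order,
    deg_gene_coverage,
    deg_proportion_matrix,
    group_association,
    normalize_intervals,
    read_peaks,
    standardize_matrix,
    window_coverage,
)
from subtelo.genome import GeneRecord, SubtelomereWindow


def per_base_coverage_oracle(intervals, start, end):
    """Covered bases in [start, end) via an explicit boolean mask."""
    mask = np.zeros(end - start, dtype=bool)
    for s, e in intervals:
        s, e = max(s, start), min(e, end)
        if s < e:
            mask[s - start:e - start] = True
    return int(mask.sum())


class TestNormalizeIntervals:
    def test_overlapping_merge(self):
        ivs = normalize_intervals([("c", 10, 20), ("c", 15, 30)])
        assert ivs.intervals["c"].tolist() == [[10, 30]]

    def test_bookended_merge(self):
        ivs = normalize_intervals([("c", 10, 20), ("c", 20, 30)])
        assert ivs.intervals["c"].tolist() == [[10, 30]]

    def test_idempotent_on_disjoint_input(self):
        raw = [("c", 0, 5), ("c", 10, 15), ("c", 20, 30)]
        once = normalize_intervals(raw)
        again = normalize_intervals(
            [("c", int(s), int(e)) for s, e in once.intervals["c"]]
        )
        assert once.intervals["c"].tolist() == again.intervals["c"].tolist()
        assert once.total_length() == 20

    def test_negative_coordinate_errors(self):
        with pytest.raises(ChromatinError, match="negative"):
            normalize_intervals([("c", -1, 10)])

    def test_narrowpeak_reader_ignores_extra_columns(self, tmp_path):
        (tmp_path / "f.narrowPeak").write_text(
            "c\t10\t20\tpk0\t100\t.\t3.2\t-1\t-1\t5\n"
            "c\t15\t40\tpk1\t90\t.\t2.0\t-1\t-1\t7\n"
        )
        ivs = read_peaks(tmp_path / "f.narrowPeak")
        assert ivs.intervals["c"].tolist() == [[10, 40]]


class TestCoverage:
    window = SubtelomereWindow("cp", "c", 0, 10_000)

    def test_half_covered_window(self):
        peaks = normalize_intervals([("c", 0, 5_000)])
        assert window_coverage(peaks, self.window) == pytest.approx(50.0)

    def test_no_overlap_is_zero(self):
        peaks = normalize_intervals([("c", 20_000, 30_000)])
        assert window_coverage(peaks, self.window) == 0.0

    def test_random_tracks_match_per_base_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            starts = rng.integers(0, 9_000, size=50)
            raw = [("c", int(s), int(s + rng.integers(1, 800))) for s in starts]
            peaks = normalize_intervals(raw)
            expected = 100.0 * per_base_coverage_oracle(
                peaks.intervals["c"], 0, 10_000
            ) / 10_000
            assert window_coverage(peaks, self.window) == pytest.approx(
                expected, abs=1e-9
            )

    def test_full_gene_coverage_is_100(self):
        genes = [GeneRecord("a", "c", 100, 200), GeneRecord("b", "c", 500, 900)]
        peaks = normalize_intervals([("c", 0, 1_000)])
        assert deg_gene_coverage(peaks, genes) == pytest.approx(100.0)

    def test_overlapping_genes_counted_once(self):
        # both genes span [100, 300); the shared region has one peak
        genes = [GeneRecord("a", "c", 100, 300), GeneRecord("b", "c", 200, 400)]
        peaks = normalize_intervals([("c", 200, 300)])
        # union of bodies = [100, 400) = 300 bp, covered 100 bp
        assert deg_gene_coverage(peaks, genes) == pytest.approx(100 * 100 / 300)

    def test_no_peak_overlap_is_zero(self):
        genes = [GeneRecord("a", "c", 100, 200)]
        peaks = normalize_intervals([("c", 5_000, 6_000)])
        assert deg_gene_coverage(peaks, genes) == 0.0

    def test_empty_gene_list_errors(self):
        with pytest.raises(ChromatinError, match="empty"):
            deg_gene_coverage(normalize_intervals([]), [])


class TestGroupAssociation:
    def test_separated_groups_give_positive_rho(self):
        values = {"a1": 5.0, "a2": 6.0, "a3": 1.0, "a4": 2.0}
        labels = {"a1": "enriched", "a2": "enriched", "a3": "other", "a4": "other"}
        rho, p = group_association(values, labels)
        assert rho > 0

    def test_constant_vector_has_no_correlation(self):
        values = {"a1": 2.0, "a2": 2.0, "a3": 2.0}
        labels = {"a1": "enriched", "a2": "other", "a3": "other"}
        rho, p = group_association(values, labels)
        assert np.isnan(rho) and np.isnan(p)

    def test_permuted_labels_center_on_zero(self):
        rng = np.random.default_rng(7)
        arms = [f"a{i}" for i in range(16)]
        values = {a: float(rng.random()) for a in arms}
        rhos = []
        for _ in range(500):
            perm = rng.permutation(16)
            labels = {
                arms[i]: "enriched" if rank < 8 else "other"
                for rank, i in enumerate(perm)
            }
            rho, _ = group_association(values, labels)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_single_group_errors(self):
        values = {"a1": 1.0, "a2": 2.0, "a3": 3.0}
        labels = {a: "enriched" for a in values}
        with pytest.raises(ChromatinError, match="non-empty"):
            group_association(values, labels)


class TestMatrices:
    def test_proportions_from_counts(self):
        counts = pd.DataFrame([[2, 3, 5]], index=["ds"], columns=["a", "b", "c"])
        props = deg_proportion_matrix(counts)
        assert props.loc["ds"].tolist() == pytest.approx([20.0, 30.0, 50.0])

    def test_all_on_one_arm(self):
        counts = pd.DataFrame([[7, 0, 0]], index=["ds"], columns=["a", "b", "c"])
        assert deg_proportion_matrix(counts).loc["ds"].tolist() == [100.0, 0.0, 0.0]

    def test_rows_always_sum_to_100(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(1, 50, size=(10, 6)))
        assert deg_proportion_matrix(counts).sum(axis=1).to_numpy() == pytest.approx(
            np.full(10, 100.0), abs=1e-9
        )

    def test_zero_row_dropped_with_warning(self, caplog):
        counts = pd.DataFrame(
            [[1, 1], [0, 0]], index=["keep", "drop"], columns=["a", "b"]
        )
        with caplog.at_level("WARNING", logger="subtelo"):
            props = deg_proportion_matrix(counts)
        assert list(props.index) == ["keep"]
        assert "drop" in caplog.text

    def test_standardize_simple_column(self):
        m = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, flat = standardize_matrix(m)
        assert z["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert flat == []

    def test_constant_column_zeroed_and_flagged(self):
        m = pd.DataFrame({"x": [1.0, 2.0], "c": [5.0, 5.0]})
        z, flat = standardize_matrix(m)
        assert (z["c"] == 0).all()
        assert flat == ["c"]

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((12, 5)))
        z, _ = standardize_matrix(m)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_single_row_errors(self):
        with pytest.raises(ChromatinError, match=">= 2 rows"):
            standardize_matrix(pd.DataFrame({"x": [1.0]}))


def complete_linkage_oracle(points):
    """Direct O(n^3) agglomeration with complete linkage (merge heights)."""
    clusters = [[i] for i in range(len(points))]
    dist = squareform(pdist(points))
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


class TestClusterOrder:
    def test_identical_rows_merge_first_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                         index=["a", "b", "c"])
        order, tree = cluster_order(m)
        assert tree[0, 2] == 0.0          # first merge height
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    def test_points_on_a_line(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["x", "y", "z"])
        _, tree = cluster_order(m)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}
        assert tree[1, 2] == pytest.approx(10.0)

    def test_merge_heights_match_direct_agglomeration_oracle(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.random((6, 4)))
        _, tree = cluster_order(m)
        assert (np.diff(tree[:, 2]) >= -1e-12).all()
        expected = complete_linkage_oracle(m.to_numpy())
        assert tree[:, 2] == pytest.approx(sorted(expected), abs=1e-9)

    def test_non_finite_values_error(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ChromatinError, match="non-finite"):
            cluster_order(m)
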