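import numpy as np
import pytest

from apmstools.core import Condition
from apmstools.qc import (
    compare_detected_counts,
    gaussian_check,
    hierarchical_cluster,
    overlap_partition,
    partition_percentages,
    pearson_matrix,
    qc_report,
    run_pca,
)

from conftest import make_table, make_two_group_design


class TestPCA:
    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        base = rng.normal(25, 2, size=(50, 3))
        t = make_table(np.hstack([base, base[:, :1]]))
        coords, _ = run_pca(t, n_components=2)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[3], atol=1e-9)

    def test_separated_groups_split_on_pc1(self, rng):
        # 30% of proteins shifted by 4 sd in the second group
        values = rng.normal(25, 1, size=(200, 12))
        values[:60, 6:] += 4.0
        coords, varexp = run_pca(make_table(values), n_components=2)
        pc1 = coords["PC1"].to_numpy()
        assert max(pc1[:6]) < min(pc1[6:]) or min(pc1[:6]) > max(pc1[6:])
        assert varexp[0] > varexp[1]

    def test_variance_fractions_bounded(self, rng):
        t = make_table(rng.normal(25, 2, size=(40, 6)))
        _, varexp = run_pca(t, n_components=5)
        assert varexp.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(varexp) <= 1e-12)

    def test_invariant_to_protein_order(self, rng):
        values = rng.normal(25, 2, size=(80, 5))
        perm = rng.permutation(80)
        c1, _ = run_pca(make_table(values), 2)
        c2, _ = run_pca(make_table(values[perm]), 2)
        # scores match up to per-component sign
        for col in c1.columns:
            assert np.allclose(c1[col], c2[col], atol=1e-8) or np.allclose(
                c1[col], -c2[col], atol=1e-8
            )

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            run_pca(make_table(rng.normal(size=(10, 1))))


class TestPearson:
    def test_unit_diagonal_and_symmetry(self, rng):
        t = make_table(rng.normal(25, 2, size=(100, 5)))
        r = pearson_matrix(t)
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)

    def test_constructed_anticorrelated_pair(self):
        x = np.linspace(20, 30, 50)
        t = make_table(np.column_stack([x, -x + 50]))
        r = pearson_matrix(t)
        assert r.iloc[0, 1] == pytest.approx(-1.0)

    def test_within_group_exceeds_between_group(self, rng):
        values = rng.normal(25, 1, size=(300, 12))
        values[:90, 6:] += 3.0  # shared signal within the bait group
        r = pearson_matrix(make_table(values)).to_numpy()
        within = np.concatenate([r[:6, :6][np.triu_indices(6, 1)],
                                 r[6:, 6:][np.triu_indices(6, 1)]])
        between = r[:6, 6:].ravel()
        assert within.mean() > between.mean()

    def test_constant_sample_rejected(self, rng):
        values = rng.normal(25, 2, size=(30, 3))
        values[:, 1] = 7.0
        with pytest.raises(ValueError, match="S1"):
            pearson_matrix(make_table(values))


class TestDetectedCounts:
    def _table_with_counts(self, counts):
        n_s = len(counts)
        n_p = max(counts)
        missing = np.ones((n_p, n_s), dtype=bool)
        for j, c in enumerate(counts):
            missing[:c, j] = False
        return make_table(np.where(missing, np.nan, 25.0), missing)

    def test_identical_groups(self):
        t = self._table_with_counts([100, 100, 100, 100, 100, 100])
        out = compare_detected_counts(t, make_two_group_design(3, 3), "BAIT_INTACT", "GST_CTRL")
        assert out["mean_diff"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_mean_difference(self):
        t = self._table_with_counts([100, 100, 100, 200, 200, 200])
        out = compare_detected_counts(t, make_two_group_design(3, 3), "BAIT_INTACT", "GST_CTRL")
        assert out["mean_diff"] == 100.0

    def test_power_with_thirty_percent_extra_detections(self, rng):
        # bait samples detect 30% more proteins; n = 6 per group
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            ctrl = rng.binomial(500, 0.6, size=6)
            bait = rng.binomial(500, 0.78, size=6)
            t = self._table_with_counts(list(ctrl) + list(bait))
            out = compare_detected_counts(
                t, make_two_group_design(6, 6), "BAIT_INTACT", "GST_CTRL"
            )
            hits += out["p_value"] < 0.05
        assert hits / n_rep >= 0.95


class TestOverlapPartition:
    def test_study_scale_percentages(self):
        # 71 control-only, 471 bait-only, 233 shared out of 775
        pct = partition_percentages(71, 471, 233)
        assert pct == {"a_only_pct": 9.16, "b_only_pct": 60.77, "shared_pct": 30.07}

    def test_percentages_sum_to_100_up_to_rounding(self, rng):
        for _ in range(50):
            a, b, s = rng.integers(0, 1000, size=3)
            if a + b + s == 0:
                continue
            pct = partition_percentages(int(a), int(b), int(s))
            assert sum(pct.values()) == pytest.approx(100.0, abs=0.02)

    def _table(self, a_only, b_only, shared):
        n = a_only + b_only + shared
        missing = np.ones((n, 2), dtype=bool)
        missing[:a_only, 0] = False
        missing[a_only:a_only + b_only, 1] = False
        missing[a_only + b_only:, :] = False
        return make_table(np.where(missing, np.nan, 25.0), missing)

    def test_counts_from_detection_masks(self):
        design = make_two_group_design(1, 1, cond_a=Condition.BAIT_INTACT)
        out = overlap_partition(self._table(71, 471, 233), design,
                                Condition.GST_CTRL, Condition.BAIT_INTACT)
        assert (out["a_only"], out["b_only"], out["shared"]) == (71, 471, 233)
        assert out["total"] == 775
        assert (out["a_only_pct"], out["b_only_pct"], out["shared_pct"]) == (
            9.16, 60.77, 30.07,
        )

    def test_disjoint_and_identical_sets(self):
        design = make_two_group_design(1, 1)
        disjoint = overlap_partition(self._table(3, 4, 0), design,
                                     Condition.GST_CTRL, Condition.BAIT_INTACT)
        assert disjoint["shared"] == 0
        identical = overlap_partition(self._table(0, 0, 5), design,
                                      Condition.GST_CTRL, Condition.BAIT_INTACT)
        assert identical["a_only"] == identical["b_only"] == 0

    def test_empty_union_rejected(self):
        design = make_two_group_design(1, 1)
        t = make_table(np.full((2, 2), np.nan), np.ones((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            overlap_partition(t, design, Condition.GST_CTRL, Condition.BAIT_INTACT)


class TestHierarchicalCluster:
    def test_exact_duplicates_merge_first_at_height_zero(self, rng):
        X = rng.normal(size=(6, 4))
        X[3] = X[0]
        res = hierarchical_cluster(X)
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2].astype(int)) == {0, 3}

    def test_merge_heights_non_decreasing(self, rng):
        res = hierarchical_cluster(rng.normal(size=(20, 5)))
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)

    def test_three_archetypes_recovered(self, rng):
        # bait-up, control-up and flat row archetypes, Z-score-like scale
        n_per = 40
        arch = np.array([
            [-1, -1, -1, 1, 1, 1],
            [1, 1, 1, -1, -1, -1],
            [0, 0, 0, 0, 0, 0],
        ], dtype=float)
        rows = np.repeat(arch, n_per, axis=0) + rng.normal(0, 0.2, size=(3 * n_per, 6))
        res = hierarchical_cluster(rows, k=3)
        labels = res.clusters
        truth = np.repeat([0, 1, 2], n_per)
        # agreement up to label permutation
        from scipy.stats import mode
        agree = sum(
            (labels[truth == g] == mode(labels[truth == g]).mode).sum() for g in range(3)
        )
        assert agree / len(labels) >= 0.95

    def test_order_is_a_permutation_and_column_axis_works(self, rng):
        X = rng.normal(size=(10, 7))
        r = hierarchical_cluster(X, axis=1)
        assert sorted(r.order.tolist()) == list(range(7))

    def test_permuted_input_same_heights(self, rng):
        X = rng.normal(size=(15, 4))
        perm = rng.permutation(15)
        h1 = hierarchical_cluster(X).linkage[:, 2]
        h2 = hierarchical_cluster(X[perm]).linkage[:, 2]
        np.testing.assert_allclose(np.sort(h1), np.sort(h2), atol=1e-9)

    def test_k_larger_than_items_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical_cluster(rng.normal(size=(3, 2)), k=5)


class TestGaussianCheck:
    def test_normal_draws_have_small_moments(self, rng):
        out = gaussian_check(rng.normal(size=10_000))
        assert abs(out["skewness"]) < 0.05
        assert abs(out["excess_kurtosis"]) < 0.1

    def test_exponential_draws_fail_normality(self, rng):
        out = gaussian_check(rng.exponential(size=10_000))
        assert out["p_value"] < 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_check(np.full(20, 3.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            gaussian_check(np.arange(5, dtype=float))


class TestQCReport:
    def test_report_assembles_all_sections(self, rng):
        values = rng.normal(25, 1, size=(120, 12))
        values[:30, 6:] += 3.0
        missing = rng.random((120, 12)) < 0.1
        raw = make_table(np.where(missing, np.nan, values), missing)
        imputed = make_table(values)
        design = make_two_group_design(6, 6)
        rep = qc_report(raw, imputed, design, "BAIT_INTACT", "GST_CTRL")
        assert set(rep) == {"pca", "pearson", "detected_counts", "overlap", "normality"}
        assert rep["overlap"]["total"] > 0
        assert set(rep["normality"]) == {"BAIT_INTACT", "GST_CTRL"}
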