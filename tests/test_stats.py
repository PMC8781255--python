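"""Statistical core: sampling, filters, imputation, scaling, PCA,
aggregation, rank tests and FDR."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from daphmsi.core import FeatureMatrix
from daphmsi.stats import (balanced_sample, bh_fdr, ellipse_outlier_filter,
                           group_filters, knn_impute, median_by_section,
                           pareto_scale, pca, rank_test)
from daphmsi.stats import test_features as run_feature_tests


def make_fm(values, groups=None, section_ids=None, times=None, treatments=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    meta = pd.DataFrame({
        "section_id": section_ids if section_ids is not None else "s1",
        "x": np.arange(1, n + 1), "y": 1,
        "time_point_h": times if times is not None else 8,
        "treatment": treatments if treatments is not None else "control",
    })
    if groups is not None:
        meta["region_label"] = groups
    mz = 100.0 + 10.0 * np.arange(values.shape[1])
    return FeatureMatrix(mz, values, meta)


class TestBalancedSample:
    def make(self, sizes):
        groups = sum(([g] * n for g, n in sizes.items()), [])
        return make_fm(np.ones((len(groups), 2)), groups)

    def test_equal_groups(self):
        fm = self.make({"a": 500, "b": 500, "c": 300, "d": 250})
        out = balanced_sample(fm, n_per_group=200, seed=0)
        counts = out.pixel_meta["region_label"].value_counts()
        assert (counts == 200).all() and out.n_pixels == 800

    def test_small_group_taken_whole(self, caplog):
        fm = self.make({"a": 150, "b": 300})
        with caplog.at_level(logging.WARNING):
            out = balanced_sample(fm, n_per_group=200, seed=0)
        counts = out.pixel_meta["region_label"].value_counts()
        assert counts["a"] == 150 and counts["b"] == 200
        assert "only 150" in caplog.text

    def test_seeded_determinism(self):
        fm = self.make({"a": 500, "b": 400})
        one = balanced_sample(fm, n_per_group=100, seed=7)
        two = balanced_sample(fm, n_per_group=100, seed=7)
        pd.testing.assert_frame_equal(one.pixel_meta, two.pixel_meta)

    def test_missing_column_errors(self):
        with pytest.raises(ValueError):
            balanced_sample(make_fm(np.ones((4, 1))), n_per_group=2)


class TestGroupFilters:
    def fixture_fm(self):
        # feature 0: 60% of "eggs", 10% elsewhere; feature 1: <=40% everywhere;
        # feature 2: fully observed
        rng = np.random.default_rng(3)
        groups = ["eggs"] * 50 + ["gut"] * 50
        values = np.full((100, 3), np.nan)
        values[:30, 0] = 1.0           # 60% of eggs
        values[50:55, 0] = 1.0         # 10% of gut
        idx = rng.choice(50, 20, replace=False)
        values[idx, 1] = 1.0           # 40% of eggs
        values[50 + rng.choice(50, 15, replace=False), 1] = 1.0  # 30% of gut
        values[:, 2] = 1.0
        return make_fm(values, groups)

    def test_group_specific_feature_kept(self):
        out = group_filters(self.fixture_fm(), "region_label", 0.5, 0.99)
        np.testing.assert_allclose(out.feature_mz, [100.0, 120.0])

    def test_low_presence_feature_removed(self):
        out = group_filters(self.fixture_fm(), "region_label", 0.5, 0.99)
        assert 110.0 not in out.feature_mz

    def test_fully_observed_unchanged(self):
        fm = make_fm(np.ones((10, 3)), ["a"] * 10)
        out = group_filters(fm, "region_label", 0.5, 0.5)
        assert out.n_pixels == 10 and out.n_features == 3

    def test_pixels_with_excess_missingness_dropped(self):
        fm = self.fixture_fm()
        out = group_filters(fm, "region_label", 0.5, 0.4)
        # retained features: 0 and 2; pixels observing only feature 2
        # (missing 50% > 40%) are dropped
        assert out.n_pixels == 35

    def test_all_removed_errors(self):
        values = np.full((10, 1), np.nan)
        values[0, 0] = 1.0
        with pytest.raises(ValueError, match="all features removed"):
            group_filters(make_fm(values, ["a"] * 10), "region_label", 0.5, 0.5)


class TestKnnImpute:
    def test_complete_matrix_identity(self):
        x = np.arange(12.0).reshape(4, 3) + 1
        np.testing.assert_array_equal(knn_impute(x, k=2), x)

    def test_identical_pixels_force_value(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, np.nan]])
        out = knn_impute(x, k=2)
        assert out[2, 1] == pytest.approx(2.0)

    def test_low_rank_beats_column_mean(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(200, 2))
        v = rng.normal(size=(2, 10))
        truth = 10 + u @ v
        x = truth.copy()
        mask = rng.random(x.shape) < 0.1
        mask[:, 0] = False  # keep every pixel observed somewhere
        x[mask] = np.nan
        knn_err = np.sqrt(np.mean((knn_impute(x, k=5)[mask] - truth[mask]) ** 2))
        col_mean = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
        mean_err = np.sqrt(np.mean((col_mean[mask] - truth[mask]) ** 2))
        assert knn_err < mean_err

    def test_feature_observed_nowhere_errors(self):
        x = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="zero pixels"):
            knn_impute(x, k=1)


class TestParetoScale:
    def test_closed_form(self):
        out = pareto_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_zeros(self):
        out = pareto_scale(np.full((4, 1), 3.0))
        np.testing.assert_array_equal(out, np.zeros((4, 1)))

    def test_columns_centered(self):
        rng = np.random.default_rng(1)
        out = pareto_scale(rng.uniform(0, 10, (50, 4)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


class TestPca:
    def test_collinear_points_rank_one(self):
        t = np.linspace(-1, 1, 20)
        x = np.column_stack([t, 2 * t, -t])
        res = pca(x, 2)
        assert res.var_explained[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_split(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20000, 2))
        res = pca(x - x.mean(axis=0), 2)
        np.testing.assert_allclose(res.var_explained, [0.5, 0.5], atol=0.02)

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 4))
        x -= x.mean(axis=0)
        res = pca(x, 4)
        np.testing.assert_allclose(res.scores @ res.loadings.T, x, atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 3))
        res = pca(x, 3)
        for j in range(3):
            col = res.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(5)
        res = pca(rng.normal(size=(40, 6)), 4)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4),
                                   atol=1e-10)

    def test_too_many_components_errors(self):
        with pytest.raises(ValueError):
            pca(np.ones((3, 2)), 3)


class TestEllipseFilter:
    def test_extreme_pixel_removed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 3))
        x[0] = 10.0  # ~10 sd away
        fm = make_fm(x - x.min() + 1.0, ["a"] * 200)
        out = ellipse_outlier_filter(fm, "region_label", conf=0.95)
        assert 1 not in out.pixel_meta["x"].tolist()

    def test_conf_near_one_removes_nothing(self):
        rng = np.random.default_rng(7)
        fm = make_fm(rng.uniform(1, 2, (100, 3)), ["a"] * 100)
        out = ellipse_outlier_filter(fm, "region_label", conf=1 - 1e-12)
        assert out.n_pixels == 100


class TestMedianBySection:
    def test_median_value(self):
        fm = make_fm(np.array([[1.0], [2.0], [9.0]]), ["eggs"] * 3)
        table = median_by_section(fm, "eggs")
        assert table.iloc[0, 0] == 2.0

    def test_one_row_per_replicate_section(self):
        values = np.ones((12, 1))
        sections = [f"s{i}" for i in range(6) for _ in range(2)]
        treatments = (["control"] * 6 + ["BPA"] * 6)
        fm = make_fm(values, ["eggs"] * 12, section_ids=sections,
                     treatments=treatments)
        table = median_by_section(fm, "eggs")
        assert len(table) == 6

    def test_unobserved_feature_stays_missing(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        fm = make_fm(values, ["eggs"] * 2)
        table = median_by_section(fm, "eggs")
        assert np.isnan(table.iloc[0, 1])


class TestRankTest:
    def test_exact_p_for_separated_triples(self):
        # U = 0; two-sided exact p = 2 * 1/C(6,3) * ... = 0.1
        stat, p = rank_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_paired_all_zero_differences(self):
        with pytest.warns(UserWarning, match="p = 1"):
            _, p = rank_test([1.0, 2.0], [1.0, 2.0], mode="paired_signed_rank")
        assert p == 1.0

    def test_all_tied_rank_sum(self):
        with pytest.warns(UserWarning):
            _, p = rank_test([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_equals_permutation_enumeration(self):
        """Exact Mann-Whitney p equals full enumeration of group
        assignments for small tie-free samples."""
        rng = np.random.default_rng(8)
        for n_a, n_b in [(3, 3), (4, 5), (6, 6)]:
            pooled = rng.permutation(rng.uniform(0, 1, n_a + n_b))
            a, b = pooled[:n_a], pooled[n_a:]
            stat, p = rank_test(a, b)
            u_obs = sum((x > y) for x in a for y in b)
            u_extreme = min(u_obs, n_a * n_b - u_obs)
            count = total = 0
            for combo in itertools.combinations(range(n_a + n_b), n_a):
                mask = np.zeros(n_a + n_b, dtype=bool)
                mask[list(combo)] = True
                u = sum((x > y) for x in pooled[mask] for y in pooled[~mask])
                total += 1
                if min(u, n_a * n_b - u) <= u_extreme:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_unequal_paired_lengths_error(self):
        with pytest.raises(ValueError):
            rank_test([1, 2], [1], mode="paired_signed_rank")


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.5] * 7), [0.5] * 7)

    def test_matches_enumeration_oracle(self):
        """Adjusted values equal the hand-rolled step-up definition:
        adj_i = min_{j >= rank(i)} (m / j) p_(j), capped at 1."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 10)))
            m = p.size
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, p[idx] * m / rank)
                expected[idx] = running
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestTestFeatures:
    def test_direction_and_fdr(self):
        rng = np.random.default_rng(10)
        n = 40
        up = np.concatenate([rng.normal(1, 0.1, n), rng.normal(3, 0.1, n)])
        down = np.concatenate([rng.normal(3, 0.1, n), rng.normal(1, 0.1, n)])
        flat = rng.normal(2, 0.1, 2 * n)
        values = np.column_stack([up, down, flat])
        treatments = ["control"] * n + ["BPA"] * n
        fm = make_fm(values, ["eggs"] * 2 * n, treatments=treatments)
        table = run_feature_tests(fm, "treatment", "control", "BPA")
        by_mz = table.set_index("feature_mz")
        assert by_mz.loc[100.0, "direction"] == 1.0
        assert by_mz.loc[110.0, "direction"] == -1.0
        assert by_mz.loc[100.0, "fdr_adjusted_p"] < 0.05
        assert by_mz.loc[120.0, "fdr_adjusted_p"] > 0.05
        assert (table["fdr_adjusted_p"] >= table["p_value"] - 1e-15).all()
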