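"""Cohort statistics, including reproduction of the published nine-subject
enzyme-activity analysis bundled with the package."""

import numpy as np
import pandas as pd
import pytest

from pasquant import datasets
from pasquant.cohort import (
    age_trend_r2,
    compare_pas_indices,
    normalize_by_reference,
    one_sided_t_test,
    summarize_groups,
    t_test_from_summary,
    z_standardize,
)

YOUNG_IDS = ["219", "309", "308", "214"]  # ages 19-29
OLD_IDS = ["302", "305", "303", "221"]  # ages 59-71


@pytest.fixture(scope="module")
def activities():
    return datasets.load_enzyme_activities()


@pytest.fixture(scope="module")
def columns(activities):
    return datasets.activity_columns(activities)


class TestNormalizeByReference:
    def test_simple_division(self):
        table = pd.DataFrame(
            {"id": ["a"], "age": [30], "sex": ["f"], "ref": [0.5], "enz": [2.0]}
        )
        out = normalize_by_reference(table, "ref")
        assert out.loc[0, "enz"] == pytest.approx(4.0)
        assert out.loc[0, "ref"] == pytest.approx(0.5)

    def test_self_normalization_gives_ones(self):
        table = pd.DataFrame(
            {"id": ["a", "b"], "age": [30, 60], "sex": ["f", "m"],
             "ref": [0.5, 2.0], "enz": [0.5, 2.0]}
        )
        out = normalize_by_reference(table, "ref")
        assert np.allclose(out["enz"], 1.0)

    def test_subject_scale_factor_cancels(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            {
                "id": [str(i) for i in range(6)],
                "age": rng.uniform(20, 70, 6),
                "sex": ["f"] * 6,
                "ref": rng.uniform(0.5, 2.0, 6),
                "e1": rng.uniform(1.0, 5.0, 6),
                "e2": rng.uniform(0.1, 0.5, 6),
            }
        )
        factor = rng.uniform(0.5, 3.0, 6)
        scaled = base.copy()
        for col in ("ref", "e1", "e2"):
            scaled[col] = base[col] * factor
        out_base = normalize_by_reference(base, "ref")
        out_scaled = normalize_by_reference(scaled, "ref")
        for col in ("e1", "e2"):
            np.testing.assert_allclose(out_base[col], out_scaled[col])

    def test_nonpositive_reference_names_subject(self):
        table = pd.DataFrame(
            {"id": ["bad"], "age": [30], "sex": ["f"], "ref": [0.0], "enz": [1.0]}
        )
        with pytest.raises(ValueError, match="bad"):
            normalize_by_reference(table, "ref")


class TestZStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(z_standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        z = z_standardize(rng.normal(5.0, 3.0, 50))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError, match="zero"):
            z_standardize([2.0, 2.0, 2.0])

    def test_t_statistic_invariant_under_standardization(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(0.0, 1.0, 10)
        z = z_standardize(np.concatenate([a, b]))
        za, zb = z[:8], z[8:]
        t_raw = one_sided_t_test(a, b).statistic
        t_std = one_sided_t_test(za, zb).statistic
        assert t_raw == pytest.approx(t_std, abs=1e-10)


class TestAgeTrend:
    @pytest.mark.parametrize(
        "position, expected", [(0, 0.21), (1, 0.43), (2, 0.42)]
    )
    def test_reproduces_published_r2_by_column_position(
        self, activities, columns, position, expected
    ):
        res = age_trend_r2(activities, columns[position])
        assert res.r2 == pytest.approx(expected, abs=0.005)

    def test_fourth_column_matches_with_median_subject_excluded(
        self, activities, columns
    ):
        res = age_trend_r2(activities, columns[3], exclude_ids=["307"])
        assert res.n == 8
        assert res.r2 == pytest.approx(0.33, abs=0.005)

    def test_perfect_line(self):
        table = pd.DataFrame(
            {"id": list("abcd"), "age": [20, 30, 40, 50], "sex": ["f"] * 4,
             "enz": [1.0, 2.0, 3.0, 4.0]}
        )
        assert age_trend_r2(table, "enz").r2 == pytest.approx(1.0)

    def test_constant_column_raises(self):
        table = pd.DataFrame(
            {"id": list("abc"), "age": [20, 30, 40], "sex": ["f"] * 3,
             "enz": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="constant"):
            age_trend_r2(table, "enz")

    def test_r_squared_consistency(self, activities, columns):
        res = age_trend_r2(activities, columns[1])
        assert res.r2 == pytest.approx(res.r**2)
        assert -1.0 <= res.r <= 1.0


class TestOneSidedT:
    def test_published_first_column_p(self, activities, columns):
        old = activities[activities["id"].isin(OLD_IDS)][columns[0]]
        young = activities[activities["id"].isin(YOUNG_IDS)][columns[0]]
        res = one_sided_t_test(old, young, variant="pooled")
        assert res.p == pytest.approx(0.07, abs=0.01)
        assert res.df == 6

    def test_third_column_p(self, activities, columns):
        old = activities[activities["id"].isin(OLD_IDS)][columns[2]]
        young = activities[activities["id"].isin(YOUNG_IDS)][columns[2]]
        res = one_sided_t_test(old, young, variant="pooled")
        assert res.p == pytest.approx(0.015, abs=0.005)

    def test_identical_groups_give_half(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        res = one_sided_t_test(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5)

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 0.5  # same spread, same n
        pooled = one_sided_t_test(a, b, variant="pooled")
        welch = one_sided_t_test(a, b, variant="welch")
        assert pooled.statistic == pytest.approx(welch.statistic, abs=1e-12)
        assert pooled.df == pytest.approx(welch.df, abs=1e-9)

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            one_sided_t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero variance"):
            one_sided_t_test([1.0, 1.0], [1.0, 1.0])


class TestTTestFromSummary:
    def test_published_glucose_uptake_p(self):
        gu = datasets.load_gu_fractions()
        row_o = gu[(gu.subset == "gu_high") & (gu.group == "old")].iloc[0]
        row_y = gu[(gu.subset == "gu_high") & (gu.group == "young")].iloc[0]
        res = t_test_from_summary(
            row_o.mean_pct, row_o.sd_pct, int(row_o.n),
            row_y.mean_pct, row_y.sd_pct, int(row_y.n),
            variant="welch",
        )
        assert res.p == pytest.approx(0.02, abs=0.01)
        assert res.statistic == pytest.approx(2.34, abs=0.01)
        assert res.df == pytest.approx(7.9, abs=0.1)

    def test_equal_summaries_give_half(self):
        res = t_test_from_summary(1.0, 0.5, 5, 1.0, 0.5, 5)
        assert res.p == pytest.approx(0.5)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_agrees_with_raw_data_test(self, variant):
        rng = np.random.default_rng(4)
        a = rng.normal(2.0, 1.0, 7)
        b = rng.normal(1.0, 2.0, 5)
        raw = one_sided_t_test(a, b, variant=variant)
        summ = t_test_from_summary(
            a.mean(), a.std(ddof=1), len(a),
            b.mean(), b.std(ddof=1), len(b),
            variant=variant,
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-10)
        assert raw.p == pytest.approx(summ.p, abs=1e-10)
        assert raw.df == pytest.approx(summ.df, abs=1e-9)


class TestSummarizeGroups:
    def test_reproduces_published_group_means(self, activities, columns):
        s = summarize_groups(activities, exclude_ids=["307"])
        assert s.old_mean[columns[2]] == pytest.approx(16.64, abs=0.005)
        assert s.young_mean[columns[4]] == pytest.approx(13.77, abs=0.005)
        assert s.old_mean[columns[0]] == pytest.approx(0.76, abs=0.0051)

    def test_reproduces_published_overall_statistics(self, activities, columns):
        s = summarize_groups(activities)
        assert s.overall_mean[columns[2]] == pytest.approx(10.63, abs=0.005)
        assert s.overall_sd[columns[2]] == pytest.approx(7.53, abs=0.005)

    def test_group_membership(self, activities):
        s = summarize_groups(activities, exclude_ids=["307"])
        assert sorted(s.young_ids) == sorted(YOUNG_IDS)
        assert sorted(s.old_ids) == sorted(OLD_IDS)
        assert "307" not in s.young_ids + s.old_ids

    def test_empty_group_raises(self, activities):
        with pytest.raises(ValueError, match="empty"):
            summarize_groups(activities, young_max_age=10.0)


class TestComparePasIndices:
    def test_fold_change_arithmetic(self):
        res = compare_pas_indices([0.1] * 5 + [0.11] * 5, [0.35] * 5 + [0.385] * 5)
        assert res.fold_change == pytest.approx(3.5)

    def test_identical_distributions_null(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 0.3, 30)
        res = compare_pas_indices(vals, vals.copy())
        assert res.fold_change == pytest.approx(1.0)
        assert res.t.p == pytest.approx(0.5)

    def test_outlier_fraction(self):
        young = [0.1, 0.2, 0.3]
        old = [0.25, 0.35, 0.4, 0.5]
        res = compare_pas_indices(young, old)
        assert res.old_outlier_fraction == pytest.approx(0.75)

    def test_zero_young_mean_raises(self):
        with pytest.raises(ValueError, match="young mean"):
            compare_pas_indices([0.0, 0.0], [0.1, 0.2])


class TestAffineInvariance:
    def test_t_and_r2_invariant_under_affine_maps(self, activities, columns):
        col = columns[1]
        young = activities[activities["id"].isin(YOUNG_IDS)][col].to_numpy()
        old = activities[activities["id"].isin(OLD_IDS)][col].to_numpy()
        t0 = one_sided_t_test(old, young).statistic
        r0 = age_trend_r2(activities, col).r2
        for a, b in [(2.0, 0.0), (0.5, 3.0), (10.0, -1.0)]:
            mapped = activities.copy()
            mapped[col] = a * activities[col] + b
            t1 = one_sided_t_test(a * old + b, a * young + b).statistic
            r1 = age_trend_r2(mapped, col).r2
            assert t1 == pytest.approx(t0, abs=1e-10)
            assert r1 == pytest.approx(r0, abs=1e-10)
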