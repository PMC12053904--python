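"""Seasonal baseline model: fitting, Type II ANOVA, intervals, flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tideline.anomaly import (SeasonalBaselineModel, flag_residuals,
                              interval_from_residuals)
from tideline.errors import DataError
from tideline.tables import make_metadata


def md_from(dates, post_from=None):
    dates = pd.to_datetime(list(dates))
    period = ["post" if post_from is not None and d >= pd.Timestamp(post_from)
              else "baseline" for d in dates]
    return make_metadata([f"s{i}" for i in range(len(dates))], dates,
                         stage=["pre"] * len(dates), period=period)


def dummy_rss(z, years, months, include_year, include_month):
    """Oracle: RSS from an independent dummy-coded least-squares refit."""
    n = len(z)
    cols = [np.ones(n)]
    if include_year:
        for lev in sorted(set(years))[1:]:
            cols.append((np.asarray(years) == lev).astype(float))
    if include_month:
        for lev in sorted(set(months))[1:]:
            cols.append((np.asarray(months) == lev).astype(float))
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, z, rcond=None)
    r = z - x @ beta
    return float(r @ r)


def random_design(rng, n=40, n_years=4, n_months=5):
    """Random unbalanced design guaranteed to have every level populated."""
    while True:
        years = rng.integers(2011, 2011 + n_years, size=n)
        months = rng.integers(1, 1 + n_months, size=n)
        if len(set(years)) == n_years and len(set(months)) == n_months:
            seen: dict = {}
            dates = []
            for y, m in zip(years, months):
                day = seen.get((y, m), 0) + 1
                seen[(y, m)] = day
                dates.append(f"{y}-{m:02d}-{day:02d}")
            return years, months, dates


class TestBaselineFit:
    def test_noiseless_recovery(self):
        years = [2011, 2012]
        months = [1, 2, 3]
        dates, zvals = [], []
        y_eff = {2011: 0.4, 2012: -0.4}
        m_eff = {1: -0.3, 2: 0.1, 3: 0.2}
        for y in years:
            for m in months:
                for d in (5, 20):
                    dates.append(f"{y}-{m:02d}-{d:02d}")
                    zvals.append(y_eff[y] + m_eff[m])
        md = md_from(dates)
        z = pd.DataFrame({"feat": zvals}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        for y in years:
            assert res.year_effects.loc[y, "feat"] == pytest.approx(y_eff[y], abs=1e-9)
        for m in months:
            assert res.month_effects.loc[m, "feat"] == pytest.approx(m_eff[m], abs=1e-9)
        np.testing.assert_allclose(res.residuals["feat"], 0.0, atol=1e-9)

    def test_balanced_design_equals_cell_mean_closed_form(self, rng):
        dates, rows = [], []
        for y in (2011, 2012):
            for m in (1, 2):
                for d in (5, 20):
                    dates.append(f"{y}-{m:02d}-{d:02d}")
        md = md_from(dates)
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        grand = z["f"].mean()
        for sid in md.index:
            y, m = md.loc[sid, "year"], md.loc[sid, "month"]
            row = z["f"][md["year"] == y].mean() - grand
            col = z["f"][md["month"] == m].mean() - grand
            assert res.fitted.loc[sid, "f"] == pytest.approx(grand + row + col,
                                                             abs=1e-9)

    def test_fitted_plus_residual_reproduces_observation(self, rng):
        years, months, dates = random_design(rng)
        md = md_from(dates)
        z = pd.DataFrame(rng.normal(size=(len(md), 3)), index=md.index,
                         columns=list("abc"))
        res = SeasonalBaselineModel(z, md).fit()
        np.testing.assert_allclose((res.fitted + res.residuals).to_numpy(),
                                   z.to_numpy(), atol=1e-9)
        # sum-to-zero constraints
        np.testing.assert_allclose(res.year_effects.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.month_effects.sum(axis=0), 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_factor_indicators(self, rng):
        years, months, dates = random_design(rng, n=60)
        md = md_from(dates)
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        r = res.residuals["f"].to_numpy()
        for lev in set(years):
            assert abs(r @ (np.asarray(years) == lev)) < 1e-8
        for lev in set(months):
            assert abs(r @ (np.asarray(months) == lev)) < 1e-8

    def test_single_level_factor_rejected(self):
        md = md_from(["2011-01-05", "2011-02-05", "2011-03-05", "2011-04-05"])
        z = pd.DataFrame({"f": [1.0, 2.0, 1.5, 2.5]}, index=md.index)
        with pytest.raises(DataError, match="single level"):
            SeasonalBaselineModel(z, md).fit()

    def test_aliased_levels_rejected(self):
        # year 2012 sampled only in month 3 and month 3 only in 2012
        md = md_from(["2011-01-05", "2011-01-20", "2011-02-05", "2011-02-20",
                      "2012-03-05", "2012-03-20"])
        z = pd.DataFrame({"f": np.arange(6.0)}, index=md.index)
        with pytest.raises(DataError, match="rank-deficient"):
            SeasonalBaselineModel(z, md).fit()

    def test_baseline_only_scope_scores_unseen_year_with_zero_effect(self, rng):
        dates = [f"{y}-{m:02d}-10" for y in (2011, 2012) for m in range(1, 7)]
        dates += [f"2013-{m:02d}-10" for m in range(1, 7)]
        md = md_from(dates, post_from="2013-01-01")
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md, fit_scope="baseline_only").fit()
        assert 2013 not in res.year_effects.index
        post = md.index[md["period"] == "post"]
        for sid in post:
            m = md.loc[sid, "month"]
            expect = res.intercept["f"] + res.month_effects.loc[m, "f"]
            assert res.fitted.loc[sid, "f"] == pytest.approx(expect, abs=1e-9)


class TestTypeTwoAnova:
    def test_balanced_equals_sequential_in_both_orders(self, rng):
        dates = [f"{y}-{m:02d}-{d:02d}" for y in (2011, 2012, 2013)
                 for m in (1, 2, 3, 4) for d in (5, 20)]
        md = md_from(dates)
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        an = res.anova().loc["f"]
        zv = z["f"].to_numpy()
        years, months = md["year"].to_numpy(), md["month"].to_numpy()
        rss_1 = dummy_rss(zv, years, months, False, False)
        rss_y = dummy_rss(zv, years, months, True, False)
        rss_m = dummy_rss(zv, years, months, False, True)
        rss_ym = dummy_rss(zv, years, months, True, True)
        # sequential year-first and month-first give the same SS when balanced
        assert an["ss_year"] == pytest.approx(rss_1 - rss_y, abs=1e-8)
        assert an["ss_year"] == pytest.approx(rss_m - rss_ym, abs=1e-8)
        assert an["ss_month"] == pytest.approx(rss_1 - rss_m, abs=1e-8)
        assert an["ss_month"] == pytest.approx(rss_y - rss_ym, abs=1e-8)

    def test_unbalanced_matches_model_comparison_oracle(self, rng):
        for _ in range(10):
            years, months, dates = random_design(rng)
            md = md_from(dates)
            z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
            res = SeasonalBaselineModel(z, md).fit()
            an = res.anova().loc["f"]
            zv = z["f"].to_numpy()
            rss_y = dummy_rss(zv, years, months, True, False)
            rss_m = dummy_rss(zv, years, months, False, True)
            rss_ym = dummy_rss(zv, years, months, True, True)
            assert an["ss_year"] == pytest.approx(rss_m - rss_ym, abs=1e-8)
            assert an["ss_month"] == pytest.approx(rss_y - rss_ym, abs=1e-8)
            assert an["ss_residual"] == pytest.approx(rss_ym, abs=1e-8)

    def test_matches_statsmodels_type_two(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        years, months, dates = random_design(rng, n=50)
        md = md_from(dates)
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        an = res.anova().loc["f"]
        df = pd.DataFrame({"z": z["f"].to_numpy(), "year": years, "month": months})
        ref = anova_lm(smf.ols("z ~ C(year) + C(month)", df).fit(), typ=2)
        assert an["ss_year"] == pytest.approx(ref.loc["C(year)", "sum_sq"], rel=1e-8)
        assert an["ss_month"] == pytest.approx(ref.loc["C(month)", "sum_sq"], rel=1e-8)
        assert an["p_year"] == pytest.approx(ref.loc["C(year)", "PR(>F)"], abs=1e-10)

    def test_null_p_values_uniform(self, rng):
        years, months, dates = random_design(rng, n=48)
        md = md_from(dates)
        z = pd.DataFrame(rng.normal(size=(len(md), 400)), index=md.index,
                         columns=[f"f{i}" for i in range(400)])
        an = SeasonalBaselineModel(z, md).fit().anova()
        ks = stats.kstest(an["p_year"], "uniform")
        assert ks.pvalue > 0.01

    def test_balanced_variance_decomposition(self, rng):
        dates = [f"{y}-{m:02d}-{d:02d}" for y in (2011, 2012)
                 for m in (1, 2, 3) for d in (5, 20)]
        md = md_from(dates)
        z = pd.DataFrame({"f": rng.normal(size=len(md))}, index=md.index)
        res = SeasonalBaselineModel(z, md).fit()
        an = res.anova().loc["f"]
        total_ss = ((z["f"] - z["f"].mean()) ** 2).sum()
        assert an["ss_year"] + an["ss_month"] + an["ss_residual"] == pytest.approx(
            total_ss, abs=1e-8)


class TestBaselineInterval:
    def _resid(self, values, ids=None):
        ids = ids or [f"s{i}" for i in range(len(values))]
        return pd.DataFrame({"f": values}, index=ids)

    def test_quantile_bounds_match_sort_oracle(self, rng):
        vals = rng.permutation(np.arange(1.0, 101.0))
        resid = self._resid(vals)
        iv = interval_from_residuals(resid, resid.index, level=0.95,
                                     exclusion_threshold=np.inf)
        lo, hi = np.quantile(np.sort(vals), [0.025, 0.975])
        assert iv.bounds.loc["f", "lower"] == pytest.approx(lo, abs=1e-12)
        assert iv.bounds.loc["f", "upper"] == pytest.approx(hi, abs=1e-12)

    def test_signed_exclusion_counts(self, rng):
        vals = np.concatenate([rng.normal(size=30), [5.0, -5.0]])
        iv = interval_from_residuals(self._resid(vals), [f"s{i}" for i in
                                                         range(len(vals))],
                                     exclusion_threshold=4.0)
        # only the +5 is excluded; -5 is kept (signed rule)
        assert iv.bounds.loc["f", "n_excluded"] == 1
        assert iv.bounds.loc["f", "n_baseline"] == len(vals) - 1

    def test_symmetric_residuals_give_symmetric_bounds(self):
        vals = np.concatenate([np.linspace(-3, 3, 61)])
        iv = interval_from_residuals(self._resid(vals), [f"s{i}" for i in
                                                         range(len(vals))])
        assert iv.bounds.loc["f", "lower"] == pytest.approx(
            -iv.bounds.loc["f", "upper"], abs=1e-9)

    def test_too_few_retained_rejected(self):
        iv_resid = self._resid([10.0, 11.0, 12.0])
        with pytest.raises(DataError, match="fewer than 2"):
            interval_from_residuals(iv_resid, iv_resid.index,
                                    exclusion_threshold=4.0)

    def test_few_retained_warns_unstable(self, rng):
        resid = self._resid(rng.normal(size=10))
        with pytest.warns(UserWarning, match="unstable"):
            interval_from_residuals(resid, resid.index)


class TestFlagging:
    def _setup(self, rng):
        vals = rng.permutation(np.arange(1.0, 101.0))
        base_ids = [f"s{i}" for i in range(100)]
        resid = pd.DataFrame({"f": vals}, index=base_ids)
        iv = interval_from_residuals(resid, base_ids, exclusion_threshold=np.inf)
        return resid, iv

    def test_boundary_equality_is_normal(self, rng):
        resid, iv = self._setup(rng)
        lo, hi = iv.bounds.loc["f", ["lower", "upper"]]
        q = pd.DataFrame({"f": [hi, lo, hi + 1e-9, lo - 1e-9]},
                         index=["q1", "q2", "q3", "q4"])
        md = md_from(["2021-01-05", "2021-01-12", "2021-01-19", "2021-01-26"],
                     post_from="2021-01-01")
        md.index = ["q1", "q2", "q3", "q4"]
        rep = flag_residuals(q, iv, md).set_index("sample_id")
        assert rep.loc["q1", "flag"] == "normal"
        assert rep.loc["q2", "flag"] == "normal"
        assert rep.loc["q3", "flag"] == "high"
        assert rep.loc["q4", "flag"] == "low"

    def test_missing_query_sample_rejected(self, rng):
        resid, iv = self._setup(rng)
        md = md_from(["2021-01-05"])
        with pytest.raises(DataError, match="not in fit"):
            flag_residuals(resid, iv, md, query_sample_ids=["nope"])


class TestModuleMedians:
    def _results(self, rng, n=24, kos=6):
        dates = [f"{2011 + i // 12}-{i % 12 + 1:02d}-10" for i in range(n)]
        md = md_from(dates)
        z = pd.DataFrame(rng.normal(size=(n, kos)), index=md.index,
                         columns=[f"K{j}" for j in range(kos)])
        return SeasonalBaselineModel(z, md).fit()

    def test_single_member_module_equals_ko_residual(self, rng):
        from tideline.tables import FeatureMap
        res = self._results(rng)
        fmap = FeatureMap.from_pairs([("K0", "M0")])
        med = res.module_median_residuals(fmap)
        pd.testing.assert_series_equal(med["M0"], res.residuals["K0"],
                                       check_names=False)

    def test_median_is_robust_and_matches_brute_force(self, rng):
        from tideline.tables import FeatureMap
        res = self._results(rng, kos=6)
        fmap = FeatureMap.from_pairs(
            [("K0", "M0"), ("K1", "M0"), ("K2", "M0"),
             ("K3", "M1"), ("K4", "M1"), ("K5", "M1"), ("K0", "M1")])
        med = res.module_median_residuals(fmap)
        for sid in res.residuals.index:
            expect = np.median([res.residuals.loc[sid, k] for k in
                                ("K3", "K4", "K5", "K0")])
            assert med.loc[sid, "M1"] == pytest.approx(expect, abs=1e-12)

    def test_median_of_skewed_triplet(self):
        assert np.median([-1.0, 0.0, 5.0]) == 0.0  # documents the convention

    def test_empty_module_rejected(self, rng):
        from tideline.tables import FeatureMap
        res = self._results(rng)
        fmap = FeatureMap.from_pairs([("K0", "M0"), ("missingKO", "Mempty")])
        with pytest.raises(DataError, match="Mempty"):
            res.module_median_residuals(fmap)


class TestMonthlyPanel:
    def _fit(self, rng):
        dates = [f"{y}-{m:02d}-{d:02d}" for y in range(2011, 2014)
                 for m in (1, 10) for d in (5, 20)]
        dates += ["2014-10-10", "2014-10-25"]
        md = md_from(dates, post_from="2014-01-01")
        z = pd.DataFrame(rng.normal(size=(len(md), 2)), index=md.index,
                         columns=["fa", "fb"])
        res = SeasonalBaselineModel(z, md).fit()
        iv = res.baseline_interval(exclusion_threshold=np.inf)
        return res, res.flag_anomalies(iv)

    def test_post_sample_appears_only_in_its_month(self, rng):
        res, rep = self._fit(rng)
        panel = res.monthly_anomaly_panel(rep)
        post = panel[panel["period"] == "post"]
        assert set(post["month"]) == {10}

    def test_months_without_post_samples_omitted(self, rng):
        res, rep = self._fit(rng)
        panel = res.monthly_anomaly_panel(rep)
        assert set(panel["month"]) == {10}   # January has no post samples

    def test_counts_match_group_by_tally(self, rng):
        res, rep = self._fit(rng)
        panel = res.monthly_anomaly_panel(rep, exclusion_threshold=np.inf)
        rep2 = rep.copy()
        rep2["month"] = pd.to_datetime(rep2["date"]).dt.month
        expect = rep2[rep2["month"] == 10]
        assert len(panel) == len(expect)
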