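"""Seasonal-baseline disturbance detection.

The detector asks whether post-disturbance samples fall outside the
envelope of natural fluctuation established by a multi-year baseline.
For each feature (taxonomic family or KEGG Ortholog), centered-and-
scaled abundances are regressed on additive categorical year and month
effects (ordinary least squares, sum-to-zero coding).  The fitted
values capture interannual plus seasonal variability; the residuals
are the natural fluctuations.  A Type II ANOVA partitions the variance
between the two factors.  An empirical 95% interval of the
baseline-period residuals then classifies each query residual as
``low``, ``normal`` or ``high`` — strictly outside the interval counts
as anomalous.

The public surface follows the Model/Results convention:
``SeasonalBaselineModel(z, metadata).fit()`` returns a
:class:`SeasonalBaselineResults` carrying effects, residuals and the
diagnostic methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UsageError
from .structure import ScaledMatrix, center_scale
from .tables import FeatureMap, FeatureTable

log = logging.getLogger("tideline")

__all__ = ["SeasonalBaselineModel", "SeasonalBaselineResults", "BaselineInterval",
           "interval_from_residuals", "flag_residuals"]


def _sum_zero_design(values: pd.Series, prefix: str) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effect) coded design block for one categorical factor.

    Returns the n x (L-1) block and the ordered level list.  The last
    level's effect is minus the sum of the others.
    """
    levels = sorted(pd.unique(values))
    if len(levels) < 2:
        raise DataError(f"baseline fit: factor {prefix!r} has a single level "
                        f"({levels}); need >= 2")
    arr = np.zeros((len(values), len(levels) - 1))
    vals = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        arr[vals == lev, j] = 1.0
    arr[vals == levels[-1], :] = -1.0
    return arr, levels


def _rss(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of z regressed on x (via QR)."""
    q, _ = np.linalg.qr(x)
    proj = q.T @ z
    return (z**2).sum(axis=0) - (proj**2).sum(axis=0)


class SeasonalBaselineModel:
    """OLS of scaled abundances on categorical year + month effects.

    Parameters
    ----------
    z : ScaledMatrix or DataFrame
        Samples x features matrix of z-scored abundances.
    metadata : DataFrame
        Indexed by sample_id with ``date``, ``year``, ``month``,
        ``period`` columns.
    fit_scope : {"all", "baseline_only"}
        ``all`` (default) fits on every sample jointly; the baseline
        interval is still computed from baseline-period residuals only.
        ``baseline_only`` fits on baseline samples and scores post
        samples with a zero year effect for unseen years (logged).
    """

    def __init__(self, z: ScaledMatrix | pd.DataFrame, metadata: pd.DataFrame,
                 fit_scope: str = "all"):
        if fit_scope not in ("all", "baseline_only"):
            raise UsageError(f"fit_scope must be all|baseline_only, got {fit_scope!r}")
        self.z = z.z if isinstance(z, ScaledMatrix) else z
        missing = [s for s in self.z.index if s not in metadata.index]
        if missing:
            raise DataError(f"baseline fit: samples without metadata: {missing}")
        self.metadata = metadata.loc[self.z.index]
        self.fit_scope = fit_scope

    @classmethod
    def from_table(cls, table: FeatureTable, metadata: pd.DataFrame,
                   fit_scope: str = "all") -> "SeasonalBaselineModel":
        """Center-and-scale a feature table, then build the model."""
        return cls(center_scale(table), metadata, fit_scope=fit_scope)

    def fit(self) -> "SeasonalBaselineResults":
        md = self.metadata
        fit_mask = (md["period"] == "baseline") if self.fit_scope == "baseline_only" \
            else pd.Series(True, index=md.index)
        if fit_mask.sum() < 4:
            raise DataError("baseline fit: too few samples in fit scope")
        md_fit = md.loc[fit_mask]
        z_fit = self.z.loc[fit_mask].to_numpy(dtype=float)

        xy, year_levels = _sum_zero_design(md_fit["year"], "year")
        xm, month_levels = _sum_zero_design(md_fit["month"], "month")
        n = len(md_fit)
        x_full = np.hstack([np.ones((n, 1)), xy, xm])
        if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
            raise DataError(
                "baseline fit: rank-deficient year+month design; aliased levels among "
                f"years {year_levels} / months {month_levels}")
        coef, *_ = np.linalg.lstsq(x_full, z_fit, rcond=None)

        ky, km = len(year_levels) - 1, len(month_levels) - 1
        intercept = coef[0]
        b_year = coef[1:1 + ky]
        b_month = coef[1 + ky:1 + ky + km]
        year_eff = np.vstack([b_year, -b_year.sum(axis=0, keepdims=True)])
        month_eff = np.vstack([b_month, -b_month.sum(axis=0, keepdims=True)])
        year_effects = pd.DataFrame(year_eff, index=year_levels, columns=self.z.columns)
        month_effects = pd.DataFrame(month_eff, index=month_levels, columns=self.z.columns)

        # fitted values for *all* samples (unseen years get zero effect)
        unseen_years = sorted(set(md["year"]) - set(year_levels))
        if unseen_years:
            log.warning("baseline fit: years %s absent from fit scope; "
                        "scored with zero year effect", unseen_years)
        ye = year_effects.reindex(md["year"]).fillna(0.0).to_numpy()
        unseen_months = sorted(set(md["month"]) - set(month_levels))
        if unseen_months:
            log.warning("baseline fit: months %s absent from fit scope; "
                        "scored with zero month effect", unseen_months)
        me = month_effects.reindex(md["month"]).fillna(0.0).to_numpy()
        fitted = pd.DataFrame(intercept[None, :] + ye + me,
                              index=self.z.index, columns=self.z.columns)
        residuals = self.z - fitted

        return SeasonalBaselineResults(
            model=self, intercept=pd.Series(intercept, index=self.z.columns),
            year_effects=year_effects, month_effects=month_effects,
            fitted=fitted, residuals=residuals,
            _fit_mask=fit_mask, _x_parts=(np.ones((n, 1)), xy, xm), _z_fit=z_fit,
            _dfs=(ky, km, n - 1 - ky - km))


@dataclass
class BaselineInterval:
    """Per-feature empirical (or normal-theory) baseline interval."""

    bounds: pd.DataFrame   # feature -> lower, upper, n_baseline, n_excluded
    level: float
    exclusion_threshold: float
    kind: str


def interval_from_residuals(residuals: pd.DataFrame, baseline_ids,
                            level: float = 0.95,
                            exclusion_threshold: float = 4.0,
                            kind: str = "empirical") -> BaselineInterval:
    """Baseline interval from a samples x features residual frame.

    Retains baseline-period residuals whose *signed* value is at most
    ``exclusion_threshold``; bounds are empirical type-7 quantiles at
    (1-level)/2 and 1-(1-level)/2, or mean +/- z*sd with
    ``kind="normal"``.
    """
    if kind not in ("empirical", "normal"):
        raise UsageError(f"interval kind must be empirical|normal, got {kind!r}")
    resid = residuals.loc[residuals.index.intersection(pd.Index(baseline_ids))]
    if resid.empty:
        raise DataError("baseline interval: no baseline-period samples")
    alpha = (1 - level) / 2
    rows = []
    unstable = []
    for feat in resid.columns:
        r = resid[feat].to_numpy(dtype=float)
        keep = r[r <= exclusion_threshold]
        n_exc = len(r) - len(keep)
        if len(keep) < 2:
            raise DataError(
                f"baseline interval: fewer than 2 retained residuals for {feat!r}")
        if len(keep) < 20:
            unstable.append(feat)
        if kind == "empirical":
            lo, hi = np.quantile(keep, [alpha, 1 - alpha])  # type-7 linear
        else:
            zcrit = stats.norm.ppf(1 - alpha)
            mu, sd = keep.mean(), keep.std(ddof=1)
            lo, hi = mu - zcrit * sd, mu + zcrit * sd
        rows.append((feat, lo, hi, len(keep), n_exc))
    if unstable:
        warnings.warn(
            f"baseline interval: <20 retained residuals for {len(unstable)} "
            f"features; interval unstable", stacklevel=2)
    bounds = pd.DataFrame(rows, columns=["feature", "lower", "upper",
                                         "n_baseline", "n_excluded"]
                          ).set_index("feature")
    return BaselineInterval(bounds=bounds, level=level,
                            exclusion_threshold=exclusion_threshold, kind=kind)


def flag_residuals(residuals: pd.DataFrame, interval: BaselineInterval,
                   metadata: pd.DataFrame,
                   query_sample_ids=None) -> pd.DataFrame:
    """Three-way low/normal/high flags for residuals against an interval.

    Strictly outside the bounds is anomalous; equality with a bound is
    ``normal``.  Long-format output, one row per (feature, sample).
    """
    if query_sample_ids is None:
        query_sample_ids = list(residuals.index)
    missing = [s for s in query_sample_ids if s not in residuals.index]
    if missing:
        raise DataError(f"flag: samples not in fit: {missing}")
    resid = residuals.loc[query_sample_ids]
    md = metadata.loc[query_sample_ids]
    feats = [f for f in resid.columns if f in interval.bounds.index]
    long = resid[feats].stack().rename("residual").reset_index()
    long.columns = ["sample_id", "feature", "residual"]
    long["date"] = md.loc[long["sample_id"], "date"].to_numpy()
    long["period"] = md.loc[long["sample_id"], "period"].to_numpy()
    long["lower"] = interval.bounds["lower"].loc[long["feature"]].to_numpy()
    long["upper"] = interval.bounds["upper"].loc[long["feature"]].to_numpy()
    long["flag"] = "normal"
    long.loc[long["residual"] > long["upper"], "flag"] = "high"
    long.loc[long["residual"] < long["lower"], "flag"] = "low"
    return long[["feature", "sample_id", "date", "period", "residual",
                 "lower", "upper", "flag"]]


class SeasonalBaselineResults:
    """Estimates, residuals and diagnostics of a seasonal baseline fit.

    Attributes
    ----------
    intercept, year_effects, month_effects
        Effect estimates per feature; sum-to-zero within each factor.
    fitted, residuals
        Samples x features frames; ``fitted + residuals`` reproduces
        the scaled observations.
    """

    def __init__(self, model, intercept, year_effects, month_effects, fitted,
                 residuals, _fit_mask, _x_parts, _z_fit, _dfs):
        self.model = model
        self.intercept = intercept
        self.year_effects = year_effects
        self.month_effects = month_effects
        self.fitted = fitted
        self.residuals = residuals
        self._fit_mask = _fit_mask
        self._x_parts = _x_parts
        self._z_fit = _z_fit
        self.df_year, self.df_month, self.df_resid = _dfs
        self._anova: pd.DataFrame | None = None

    # -- Type II ANOVA -------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Type II ANOVA table per feature.

        ``SS_year = RSS(month-only) - RSS(year+month)`` and symmetrically
        for month; F statistics use the full-model residual mean square.
        """
        if self._anova is not None:
            return self._anova
        ones, xy, xm = self._x_parts
        z = self._z_fit
        rss_full = _rss(np.hstack([ones, xy, xm]), z)
        rss_year_only = _rss(np.hstack([ones, xy]), z)
        rss_month_only = _rss(np.hstack([ones, xm]), z)
        ss_year = rss_month_only - rss_full
        ss_month = rss_year_only - rss_full
        ms_resid = rss_full / self.df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            f_year = (ss_year / self.df_year) / ms_resid
            f_month = (ss_month / self.df_month) / ms_resid
        p_year = stats.f.sf(f_year, self.df_year, self.df_resid)
        p_month = stats.f.sf(f_month, self.df_month, self.df_resid)
        self._anova = pd.DataFrame({
            "ss_year": ss_year, "df_year": self.df_year,
            "ss_month": ss_month, "df_month": self.df_month,
            "ss_residual": rss_full, "df_residual": self.df_resid,
            "f_year": f_year, "p_year": p_year,
            "f_month": f_month, "p_month": p_month,
        }, index=self.residuals.columns)
        return self._anova

    # -- baseline interval --------------------------------------------
    def baseline_interval(self, level: float = 0.95,
                          exclusion_threshold: float = 4.0,
                          kind: str = "empirical") -> BaselineInterval:
        """Interval of natural fluctuation from baseline-period residuals.

        Baseline residuals with signed value greater than
        ``exclusion_threshold`` are excluded (counted per feature).
        ``empirical`` bounds are the (1-level)/2 and 1-(1-level)/2
        quantiles with linear (type-7) interpolation; ``normal`` bounds
        are mean +/- z * sd.
        """
        base_ids = self.model.metadata.index[self.model.metadata["period"] == "baseline"]
        return interval_from_residuals(self.residuals, base_ids, level=level,
                                       exclusion_threshold=exclusion_threshold,
                                       kind=kind)

    # -- flagging ------------------------------------------------------
    def flag_anomalies(self, interval: BaselineInterval,
                       query_sample_ids=None) -> pd.DataFrame:
        """Classify residuals as low / normal / high against the interval.

        ``high`` means strictly above the upper bound, ``low`` strictly
        below the lower bound; equality with a bound is ``normal``.
        Returns a long-format report with one row per
        (feature, sample).
        """
        return flag_residuals(self.residuals, interval, self.model.metadata,
                              query_sample_ids)

    # -- KEGG-module medians -------------------------------------------
    def module_median_residuals(self, ko_to_module: FeatureMap) -> pd.DataFrame:
        """Median residual of member KOs per module per sample.

        Even member counts take the mean of the central pair (the
        ordinary sample median).
        """
        members: dict[str, list[str]] = {}
        for ko in self.residuals.columns:
            if ko in ko_to_module:
                for mod in ko_to_module[ko]:
                    members.setdefault(mod, []).append(ko)
        empty = [m for m in ko_to_module.parent_ids if m not in members]
        if empty:
            raise DataError(f"module_median_residuals: modules with no member KOs "
                            f"present: {empty}")
        cols = {mod: self.residuals[kos].median(axis=1) for mod, kos in
                sorted(members.items())}
        return pd.DataFrame(cols, index=self.residuals.index)

    # -- monthly panels ------------------------------------------------
    def monthly_anomaly_panel(self, report: pd.DataFrame,
                              exclusion_threshold: float = 4.0) -> pd.DataFrame:
        """Group residuals by calendar month for ridgeline-style export.

        For each month with at least one post-period sample, rows carry
        the baseline residuals (the density input, after the exclusion
        rule) and the post-period residuals with their flags.  Months
        without post samples are skipped with a log line; months
        without baseline residuals are skipped with a warning.
        """
        rep = report.copy()
        rep["month"] = pd.to_datetime(rep["date"]).dt.month
        panels = []
        for month, grp in rep.groupby("month"):
            base = grp[(grp["period"] == "baseline")
                       & (grp["residual"] <= exclusion_threshold)]
            post = grp[grp["period"] == "post"]
            if post.empty:
                log.info("monthly_anomaly_panel: month %d has no post samples; omitted",
                         month)
                continue
            if base.empty:
                warnings.warn(f"monthly_anomaly_panel: month {month} has no baseline "
                              f"residuals; omitted", stacklevel=2)
                continue
            panels.append(grp[grp.index.isin(base.index) | grp.index.isin(post.index)])
        if not panels:
            return rep.iloc[0:0]
        return pd.concat(panels, ignore_index=True)[
            ["month", "period", "feature", "sample_id", "date", "residual", "flag"]]

    # -- summary -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text overview of the fit."""
        an = self.anova()
        n, p = self.residuals.shape
        base = (self.model.metadata["period"] == "baseline").sum()
        lines = [
            "Seasonal baseline fit (OLS, year + month, sum-to-zero coding)",
            "=" * 62,
            f"samples: {n} ({base} baseline, {n - base} post)   features: {p}",
            f"fit scope: {self.model.fit_scope}",
            f"year levels: {list(self.year_effects.index)}",
            f"df: year={self.df_year}  month={self.df_month}  residual={self.df_resid}",
            f"median F(year)={np.nanmedian(an['f_year']):.3f}  "
            f"median F(month)={np.nanmedian(an['f_month']):.3f}",
            f"features with p_month<0.05: {(an['p_month'] < 0.05).sum()}  "
            f"p_year<0.05: {(an['p_year'] < 0.05).sum()}",
            f"residual sd (pooled): {float(np.sqrt(np.mean(self.residuals.to_numpy()**2))):.3f}",
        ]
        return "\n".join(lines)
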