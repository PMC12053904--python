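"""Curated oil-responder and susceptible-taxon panel tracking.

Panels are data, not code: a two-column TSV of (feature_id, role) with
role ``susceptible`` or ``responder``.  The shipped default panel
(:func:`default_panel`) lists picocyanobacteria and SAR11 as
susceptible and known hydrocarbon-degrading / opportunistic genera
from the Deepwater Horizon literature as responders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .tables import FeatureTable

__all__ = ["ResponderPanel", "default_panel", "panel_total", "panel_rescale",
           "panel_center", "pearson_screen", "bh_adjust"]

ROLES = ("susceptible", "responder")


@dataclass
class ResponderPanel:
    """Feature -> role assignment for panel operations."""

    roles: dict[str, str]

    def __post_init__(self) -> None:
        bad = {f: r for f, r in self.roles.items() if r not in ROLES}
        if bad:
            raise DataError(f"panel roles must be in {ROLES}; got {bad}")

    def features(self, role: str | None = None) -> list[str]:
        if role is None:
            return sorted(self.roles)
        return sorted(f for f, r in self.roles.items() if r == role)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ResponderPanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df["feature_id"].duplicated().any():
            raise DataError("panel: duplicate feature ids")
        return cls(dict(zip(df["feature_id"], df["role"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.roles.items()),
                     columns=["feature_id", "role"]).to_csv(path, sep="\t", index=False)


def default_panel() -> ResponderPanel:
    """The shipped Deepwater-Horizon-derived genus panel."""
    with resources.as_file(resources.files("tideline.data") / "dwh_panel.tsv") as p:
        return ResponderPanel.read_tsv(p)


def _present(table: FeatureTable, wanted: list[str], what: str) -> list[str]:
    present = [f for f in wanted if f in table.data.columns]
    missing = sorted(set(wanted) - set(present))
    if missing:
        warnings.warn(f"{what}: panel features missing from table: {missing}",
                      stacklevel=3)
    return present


def panel_total(relabund: FeatureTable, panel: ResponderPanel,
                role: str = "responder") -> pd.Series:
    """Per-sample summed relative abundance of panel features of a role."""
    if relabund.value_kind != "relative":
        raise DataError("panel_total: table must be relative abundance")
    feats = _present(relabund, panel.features(role), "panel_total")
    if not feats:
        warnings.warn("panel_total: no panel features present; totals are 0",
                      stacklevel=2)
        return pd.Series(0.0, index=relabund.data.index, name="panel_total")
    return relabund.data[feats].sum(axis=1).rename("panel_total")


def panel_rescale(relabund: FeatureTable, panel: ResponderPanel,
                  role: str = "responder") -> pd.DataFrame:
    """Within-panel composition scaled to sum to 100% per sample.

    Samples whose panel total is zero are returned as NaN rows (flagged
    missing) rather than raising.
    """
    if relabund.value_kind != "relative":
        raise DataError("panel_rescale: table must be relative abundance")
    feats = _present(relabund, panel.features(role), "panel_rescale")
    sub = relabund.data[feats]
    totals = sub.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"panel_rescale: zero panel total for samples "
                      f"{totals.index[zero].tolist()}; rows set to NaN", stacklevel=2)
    scaled = sub.div(totals.replace(0, np.nan), axis=0) * 100.0
    return scaled


def panel_center(scaled_panel: pd.DataFrame) -> pd.DataFrame:
    """Subtract each feature's mean from its rescaled (percent) series."""
    return scaled_panel.sub(scaled_panel.mean(axis=0), axis=1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def pearson_screen(relabund: FeatureTable, set_a: list[str], set_b: list[str],
                   adjust: str = "bh") -> pd.DataFrame:
    """Pearson correlations between two feature sets, BH-adjusted.

    For every (a, b) pair the two-sided p uses the t distribution with
    n - 2 df.  Zero-variance series give an undefined (NaN) pair.
    """
    a_feats = _present(relabund, list(set_a), "pearson_screen")
    b_feats = _present(relabund, list(set_b), "pearson_screen")
    rows = []
    for fa in a_feats:
        for fb in b_feats:
            sub = relabund.data[[fa, fb]].dropna()
            n = len(sub)
            x, y = sub[fa].to_numpy(float), sub[fb].to_numpy(float)
            if n < 3:
                raise DataError(f"pearson_screen: fewer than 3 complete pairs for "
                                f"({fa}, {fb})")
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append((fa, fb, n, n - 2, r, p))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "n", "df", "r", "p"])
    if adjust == "bh":
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    elif adjust in (None, "none"):
        out["p_adjusted"] = out["p"]
    else:
        raise DataError(f"pearson_screen: unknown adjustment {adjust!r}")
    return out
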