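"""Alpha-diversity: Shannon entropy, richness, Pielou evenness.

All metrics use natural logarithms, so Pielou's J = H / ln(S) is the
Shannon index over the log of richness.  Metrics are computed per
sample on aggregated RPKM values; zeros contribute nothing to H and do
not count toward S.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .tables import FeatureTable, check_table_metadata

__all__ = ["shannon", "richness", "pielou", "diversity_series",
           "metric_correlations"]


def shannon(abundances: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of a nonnegative vector."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any() or not np.isfinite(x).all():
        raise DataError("shannon: abundances must be finite and nonnegative")
    total = x.sum()
    if total <= 0:
        raise DataError("shannon: all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(abundances: np.ndarray, detection_threshold: float = 0.0) -> int:
    """Number of features with abundance strictly above the threshold."""
    x = np.asarray(abundances, dtype=float)
    return int((x > detection_threshold).sum())


def pielou(abundances: np.ndarray, detection_threshold: float = 0.0) -> float:
    """Evenness J = H / ln S.  Undefined (NaN) when S <= 1."""
    s = richness(abundances, detection_threshold)
    if s <= 1:
        return float("nan")
    return shannon(abundances) / np.log(s)


def diversity_series(table: FeatureTable, metadata: pd.DataFrame,
                     detection_threshold: float = 0.0) -> pd.DataFrame:
    """Per-sample diversity profile, ordered by collection date.

    Returns a frame indexed by sample_id with columns ``date``,
    ``shannon``, ``richness``, ``pielou``.  Samples whose metrics are
    uncomputable (all-zero rows) are flagged in an ``error`` column
    rather than raising.
    """
    check_table_metadata(table, metadata)
    order = metadata.loc[table.sample_ids, "date"].sort_values(kind="mergesort").index
    rows = []
    for sid in order:
        x = table.data.loc[sid].to_numpy(dtype=float)
        try:
            h = shannon(x)
            err = ""
        except DataError as exc:
            h, err = float("nan"), str(exc)
        s = richness(x, detection_threshold)
        j = h / np.log(s) if s > 1 and np.isfinite(h) else float("nan")
        rows.append((sid, metadata.loc[sid, "date"], h, s, j, err))
    return pd.DataFrame(rows, columns=["sample_id", "date", "shannon",
                                       "richness", "pielou", "error"]
                        ).set_index("sample_id")


def metric_correlations(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each pair of alpha-diversity metrics.

    Pairwise-complete samples; two-sided p from the t distribution with
    n - 2 degrees of freedom.  Zero-variance metrics give NaN r and p.
    """
    metrics = ["shannon", "richness", "pielou"]
    rows = []
    for i, a in enumerate(metrics):
        for b in metrics[i + 1:]:
            sub = profiles[[a, b]].dropna()
            n = len(sub)
            x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append((a, b, n, max(n - 2, 0), r, p))
    return pd.DataFrame(rows, columns=["metric_a", "metric_b", "n", "df", "r", "p"])
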