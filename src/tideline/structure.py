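"""Community structure: z-scoring, PCA, PERMANOVA, turnover, clustering.

Beta-diversity here is Euclidean distance on centered-and-scaled
abundance tables, matching a principal component analysis of the same
matrix.  PERMANOVA partitions the squared-distance matrix among group
labels and assesses the pseudo-F by label permutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, UsageError
from .tables import FeatureTable, check_table_metadata

__all__ = ["ScaledMatrix", "PcaResult", "PermanovaResult", "center_scale",
           "pca", "euclidean_distances", "permanova", "nn_dissimilarity",
           "hclust_complete"]


@dataclass
class ScaledMatrix:
    """Column z-scores of a feature table plus the scaling statistics.

    Non-constant columns have mean 0 and (n-1 denominator) sd 1;
    constant columns are set to all-zero and listed in
    ``constant_features``.
    """

    z: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    constant_features: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def values(self) -> np.ndarray:
        return self.z.to_numpy(dtype=float)


def center_scale(table: FeatureTable | pd.DataFrame, ddof: int = 1) -> ScaledMatrix:
    """Center and scale each feature column to zero mean, unit sd.

    Constant columns cannot be scaled; they become all-zero and a
    warning is emitted.  Requires at least two samples.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if len(df) < 2:
        raise DataError("center_scale: need at least 2 samples")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=ddof)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        warnings.warn(f"center_scale: {len(constant)} constant features set to zero",
                      stacklevel=2)
    safe_sd = sds.replace(0, np.nan)
    z = df.sub(means, axis=1).div(safe_sd, axis=1)
    z[constant] = 0.0
    return ScaledMatrix(z=z, means=means, sds=sds, constant_features=constant)


@dataclass
class PcaResult:
    """Principal component scores, loadings and explained variance."""

    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # features x components
    variance_explained: np.ndarray  # fractions, non-increasing

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def pca(z: ScaledMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of a z-scored matrix via singular value decomposition.

    Equivalent to classical metric scaling of the Euclidean distance
    matrix of ``z``.  Sign convention: each component is flipped so its
    largest-magnitude loading is positive, making PC1 time series
    reproducible across runs.
    """
    x = z.values
    n, p = x.shape
    if n < 2:
        raise DataError("pca: need at least 2 samples")
    max_comp = min(n, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise UsageError(f"pca: n_components {n_components} > min(dims) {max_comp}")
    xc = x - x.mean(axis=0, keepdims=True)  # z is centered already unless constant cols
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = xc.var(axis=0, ddof=1).sum()
    var_frac = eig / total if total > 0 else np.zeros_like(eig)
    # deterministic sign: largest |loading| of each component positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores[:, :n_components], index=z.z.index,
                            columns=comp_names),
        loadings=pd.DataFrame(vt[:n_components].T, index=z.z.columns,
                              columns=comp_names),
        variance_explained=var_frac[:n_components],
    )


def euclidean_distances(z: ScaledMatrix) -> pd.DataFrame:
    """Square symmetric Euclidean distance matrix between samples."""
    d = squareform(pdist(z.values, metric="euclidean"))
    return pd.DataFrame(d, index=z.z.index, columns=z.z.index)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def permanova(dist: pd.DataFrame | np.ndarray, groups, n_permutations: int | str = 999,
              seed: int | None = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``SS_total = sum_{i<j} d_ij^2 / n``; within-group sums use group
    sizes; ``pseudo-F = (SS_between/df_b) / (SS_within/df_w)``.  The p
    value counts permuted statistics ``>=`` the observed one with the
    +1 small-sample correction, so the smallest attainable p is exactly
    ``1/(n_permutations+1)``.  Pass ``n_permutations="exhaustive"`` to
    enumerate every label permutation instead (p then has no +1 term).
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise DataError("permanova: distance matrix must be square symmetric, zero diagonal")
    labels = np.asarray(list(groups))
    if len(labels) != n:
        raise DataError("permanova: one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DataError("permanova: need at least 2 groups")
    d2 = d**2
    ss_total = d2.sum() / (2 * n)
    ss_w = _ss_within(d2, labels, uniq)
    ss_b = ss_total - ss_w
    if ss_total == 0:
        raise DataError("permanova: no variation among samples")
    df_b = len(uniq) - 1
    df_w = n - len(uniq)
    if df_w <= 0:
        raise DataError("permanova: no residual degrees of freedom")

    def f_of(lab: np.ndarray) -> float:
        sw = _ss_within(d2, lab, uniq)
        sb = ss_total - sw
        if sw == 0:
            return np.inf
        return (sb / df_b) / (sw / df_w)

    f_obs = f_of(labels)
    if n_permutations == "exhaustive":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if f_of(labels[list(perm)]) >= f_obs - 1e-12:
                count += 1
        p = count / total
        n_perm_eff = total
        seed = None
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_permutations)):
            if f_of(rng.permutation(labels)) >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (int(n_permutations) + 1)
        n_perm_eff = int(n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(ss_b / ss_total), p_value=float(p),
        n_permutations=n_perm_eff, seed=seed, ss_between=float(ss_b),
        ss_within=float(ss_w), df_between=df_b, df_within=df_w)


def nn_dissimilarity(z: ScaledMatrix, metadata: pd.DataFrame,
                     tie_break: list[str] | None = None) -> pd.DataFrame:
    """Euclidean distance of each sample to its temporal predecessor.

    Samples are put in chronological order; the first sample has no
    predecessor (NaN).  Duplicate collection dates are an error unless
    a ``tie_break`` ordering of sample ids is supplied.
    """
    sids = z.sample_ids
    missing = [s for s in sids if s not in metadata.index]
    if missing:
        raise DataError(f"nn_dissimilarity: samples without metadata: {missing}")
    dates = metadata.loc[sids, "date"]
    if dates.duplicated().any() and tie_break is None:
        dups = dates[dates.duplicated(keep=False)].index.tolist()
        raise DataError(f"nn_dissimilarity: duplicate dates for {dups}; supply tie_break")
    if tie_break is not None:
        rank = {s: i for i, s in enumerate(tie_break)}
        order = sorted(sids, key=lambda s: (dates[s], rank.get(s, len(rank))))
    else:
        order = dates.sort_values(kind="mergesort").index.tolist()
    x = z.z.loc[order].to_numpy(dtype=float)
    diffs = np.linalg.norm(np.diff(x, axis=0), axis=1)
    vals = np.concatenate([[np.nan], diffs])
    return pd.DataFrame({"date": dates.loc[order].values, "nn_dissimilarity": vals},
                        index=pd.Index(order, name="sample_id"))


def hclust_complete(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Returns a SciPy-format linkage matrix; merge heights are
    non-decreasing because complete linkage is monotone.
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if d.shape[0] < 2:
        raise DataError("hclust_complete: need at least 2 items")
    return linkage(squareform(d, checks=False), method="complete")
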