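"""Indicator-feature analysis (IndVal.g) with a permutation null.

For a combination C of stage groups, specificity
``A = sum_{g in C} mean_g / sum_{all g} mean_g`` uses per-stage mean
abundances (group-size corrected), fidelity ``B`` is the fraction of
C-samples where the feature is present (abundance > 0), and the
indicator statistic is ``sqrt(A * B)``.  The best combination
maximises the statistic; significance comes from permuting stage
labels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .tables import FeatureTable

__all__ = ["indval", "select_stage_associated", "default_combinations"]


def default_combinations(stages: list[str], post_stages: set[str] | None = None
                         ) -> list[frozenset[str]]:
    """All singleton stages, plus the union of post stages if given."""
    combos = [frozenset([s]) for s in sorted(set(stages))]
    if post_stages:
        post = frozenset(post_stages)
        if 1 < len(post) < len(set(stages)) and post not in combos:
            combos.append(post)
    return combos


def _stat_matrix(x: np.ndarray, present: np.ndarray, labels: np.ndarray,
                 uniq: np.ndarray, combo_masks: np.ndarray) -> np.ndarray:
    """Indicator statistic for every (combination, feature) pair.

    ``combo_masks`` is (n_combos x n_stages) boolean.  Returns
    (n_combos x n_features).
    """
    k = len(uniq)
    w = np.zeros((k, len(labels)))
    counts = np.zeros(k)
    for i, g in enumerate(uniq):
        mask = labels == g
        counts[i] = mask.sum()
        w[i, mask] = 1.0 / mask.sum()
    means = w @ x                      # k x F per-stage means
    pres_counts = (w > 0).astype(float) @ present   # k x F presence counts
    total_mean = means.sum(axis=0)
    c_means = combo_masks @ means      # combos x F
    c_pres = combo_masks @ pres_counts
    c_n = combo_masks @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(total_mean > 0, c_means / total_mean, 0.0)
        b = c_pres / c_n[:, None]
    return np.sqrt(np.clip(a, 0, 1) * np.clip(b, 0, 1))


def indval(table: FeatureTable, stages, allowed_combinations=None,
           n_permutations: int | str = 999, seed: int | None = 0) -> pd.DataFrame:
    """IndVal.g indicator analysis of every feature against stage groups.

    Parameters
    ----------
    table : FeatureTable
        Samples x features abundances (RPKM or relative).
    stages : sequence of str
        One stage label per sample, aligned with the table rows.
    allowed_combinations : list of sets, optional
        Candidate stage combinations; defaults to all singletons.  The
        full stage set is not allowed (it carries no information).
    n_permutations : int or "exhaustive"
        Random label permutations (p gets the +1 correction) or full
        enumeration (no correction; only for small n).

    Returns
    -------
    DataFrame indexed by feature with columns ``best_combination``
    (frozenset), ``a``, ``b``, ``stat``, ``p_value``, ``absent``.
    """
    labels = np.asarray(list(stages))
    if len(labels) != table.shape[0]:
        raise DataError("indval: one stage label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DataError("indval: need >= 2 stages")
    if (counts < 2).any():
        raise DataError(f"indval: every stage needs >= 2 samples; "
                        f"sizes {dict(zip(uniq, counts))}")
    if allowed_combinations is None:
        combos = [frozenset([s]) for s in uniq]
    else:
        combos = [frozenset(c) for c in allowed_combinations]
        full = frozenset(uniq)
        for c in combos:
            if not c or not c <= full:
                raise UsageError(f"indval: combination {set(c)} not a subset of stages")
            if c == full:
                raise UsageError("indval: the full stage set is not an allowed combination")
    combo_masks = np.array([[s in c for s in uniq] for c in combos], dtype=float)

    x = table.values
    present = (x > 0).astype(float)
    obs = _stat_matrix(x, present, labels, uniq, combo_masks)
    best_idx = obs.argmax(axis=0)
    nfeat = x.shape[1]
    best_stat = obs[best_idx, np.arange(nfeat)]

    # A and B of the best combination, recomputed for reporting
    w = np.zeros((len(uniq), len(labels)))
    for i, g in enumerate(uniq):
        mask = labels == g
        w[i, mask] = 1.0 / mask.sum()
    means = w @ x
    pres_counts = (w > 0).astype(float) @ present
    total_mean = means.sum(axis=0)
    a_best = np.zeros(nfeat)
    b_best = np.zeros(nfeat)
    for j in range(nfeat):
        cm = combo_masks[best_idx[j]]
        if total_mean[j] > 0:
            a_best[j] = (cm @ means[:, j]) / total_mean[j]
        b_best[j] = (cm @ pres_counts[:, j]) / (cm @ np.array(
            [(labels == g).sum() for g in uniq], dtype=float))

    absent = x.sum(axis=0) == 0
    if n_permutations == "exhaustive":
        n = len(labels)
        if math.factorial(n) > 50_000:
            raise UsageError("indval: exhaustive enumeration infeasible for n > 8")
        count = np.zeros(nfeat)
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            s = _stat_matrix(x, present, labels[list(perm)], uniq, combo_masks)
            count += s.max(axis=0) >= best_stat - 1e-12
        p = count / total
        n_perm_eff = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(nfeat)
        for _ in range(int(n_permutations)):
            s = _stat_matrix(x, present, rng.permutation(labels), uniq, combo_masks)
            count += s.max(axis=0) >= best_stat - 1e-12
        p = (1 + count) / (int(n_permutations) + 1)
        n_perm_eff = int(n_permutations)

    p = np.where(absent, 1.0, p)
    best_stat = np.where(absent, 0.0, best_stat)
    return pd.DataFrame({
        "best_combination": [combos[i] for i in best_idx],
        "a": np.where(absent, 0.0, a_best),
        "b": np.where(absent, 0.0, b_best),
        "stat": best_stat,
        "p_value": p,
        "n_permutations": n_perm_eff,
        "absent": absent,
    }, index=pd.Index(table.feature_ids, name="feature"))


def select_stage_associated(results: pd.DataFrame, post_stages: set[str],
                            alpha: float = 0.05,
                            observed_stages: set[str] | None = None
                            ) -> tuple[list[str], list[str]]:
    """Apply the post-disturbance selection rule to indicator results.

    Returns ``(single_stage, all_stages)``: significant features whose
    best combination is a single post-disturbance stage, and those
    whose best combination is the full set of post-disturbance stages.
    """
    post = frozenset(post_stages)
    if observed_stages is not None and not post <= set(observed_stages):
        raise DataError(f"select_stage_associated: post stages {set(post)} not a "
                        f"subset of observed stages {set(observed_stages)}")
    sig = results[results["p_value"] < alpha]
    single = [f for f, c in sig["best_combination"].items()
              if len(c) == 1 and c <= post]
    union = [f for f, c in sig["best_combination"].items() if c == post]
    return single, union
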