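"""Evaluation statistics: confusion matrices and the Mann-Whitney U test.

The Mann-Whitney U test compares per-seed accuracy distributions between
feedback modes.  Small instances are solved exactly: with ties in the
pooled data the null distribution of U is enumerated over all
``C(n_a + n_b, n_a)`` group assignments of the observed values; without
ties the exact distribution comes from the standard count recursion (via
scipy).  Larger instances fall back to the normal approximation with
midrank tie correction and continuity correction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["evaluate_confusion", "mann_whitney_u"]

# Largest number of group assignments enumerated for an exact tied test.
_MAX_ENUMERATION = 200_000


def evaluate_confusion(
    predictions, labels, n_classes: int
) -> tuple[np.ndarray, float]:
    """Tally a (true x predicted) confusion matrix and overall accuracy."""
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if (
        predictions.min() < 0
        or labels.min() < 0
        or predictions.max() >= n_classes
        or labels.max() >= n_classes
    ):
        raise ValueError("label outside the class range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, predictions), 1)
    accuracy = float(np.trace(cm)) / float(cm.sum())
    return cm, accuracy


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: pairs with a > b, counting ties as one half."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum U (of ``sample_a``) and its p-value.

    Exact for small samples — by full assignment enumeration when the
    pooled data contain ties, by the exact count distribution otherwise —
    and by tie-corrected normal approximation (with continuity
    correction) for larger ones.  ``alternative`` is ``two-sided``,
    ``greater`` (a tends larger than b) or ``less``.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative '{alternative}'")
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n_a, n_b = a.size, b.size

    small = n_a * n_b <= 400
    if small and has_ties and comb(n_a + n_b, n_a) <= _MAX_ENUMERATION:
        p = _exact_p_enumeration(pooled, n_a, u_obs, alternative)
        return u_obs, p
    if small and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _exact_p_enumeration(
    pooled: np.ndarray, n_a: int, u_obs: float, alternative: str
) -> float:
    """Permutation-exact p over all assignments of the pooled values."""
    n = pooled.size
    mu = n_a * (n - n_a) / 2.0
    total = 0
    count = 0
    for idx_a in combinations(range(n), n_a):
        idx_a = np.asarray(idx_a)
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "two-sided":
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            count += u >= u_obs - 1e-12
        else:
            count += u <= u_obs + 1e-12
    return count / total
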