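"""ROC/threshold metrics and cross-repeat summary statistics."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["auc", "sens_spec", "geometric_mean", "summarize", "auc_band"]


def auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann–Whitney formulation.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)
    over all positive/negative pairs.  Positive class is label 1.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    if np.isnan(s).any():
        raise ValueError("scores contain NaN")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one sample of each class")
    ranks = rankdata(s)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def sens_spec(labels, probs, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity at a decision threshold.

    A sample is called positive iff its probability is >= ``threshold``.
    """
    y = np.asarray(labels)
    p = np.asarray(probs, dtype=float)
    pred = p >= threshold
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("sensitivity/specificity require both classes present")
    tp = int(((y == 1) & pred).sum())
    tn = int(((y == 0) & ~pred).sum())
    return tp / n_pos, tn / n_neg


def geometric_mean(values) -> float:
    """Geometric mean; zero if any value is zero, error if any is negative."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of empty sequence")
    if (v < 0).any():
        raise ValueError("geometric mean undefined for negative values")
    if (v == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


def summarize(values, ndigits: int | None = None) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    ``ndigits`` optionally rounds both statistics for reporting.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize of empty sequence")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if ndigits is not None:
        mean, sd = round(mean, ndigits), round(sd, ndigits)
    return mean, sd


def auc_band(value: float) -> str:
    """Qualitative label for an AUC value."""
    if value < 0.6:
        return "failed"
    if value < 0.7:
        return "poor"
    if value < 0.8:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"
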