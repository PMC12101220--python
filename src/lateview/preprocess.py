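"""Per-view preprocessing transforms.

Every transform takes a :class:`~lateview.containers.FeatureTable` and
returns a new one; none mutates its input.  Filters drop whole feature
columns and preserve the order of survivors, which makes them idempotent.
Transforms log input/output dimensions at DEBUG level.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable

__all__ = [
    "aggregate_taxa",
    "filter_low_total",
    "rclr",
    "lod_filter",
    "missingness_filter",
    "weight_normalize",
    "log2_transform",
    "qrilc_impute",
    "fit_censored_normal",
    "nzv_keep",
    "nzv_filter",
    "correlation_keep",
    "correlation_filter",
    "apply_recipe",
    "default_recipe",
]

log = logging.getLogger(__name__)


def _log_dims(op: str, before: FeatureTable, after: FeatureTable) -> None:
    log.debug(
        "%s: %dx%d -> %dx%d", op, before.n_samples, before.n_features,
        after.n_samples, after.n_features,
    )


def aggregate_taxa(table: FeatureTable, mapping: Mapping) -> FeatureTable:
    """Sum feature columns into groups (e.g. ASVs into genera).

    Group columns appear in first-appearance order of their members.
    Every feature must be mapped; an unmapped feature raises ``KeyError``.
    """
    unmapped = [f for f in table.feature_ids if f not in mapping]
    if unmapped:
        raise KeyError(f"features without a group mapping: {unmapped[:5]}")
    groups = pd.Series([mapping[f] for f in table.feature_ids], index=table.values.columns)
    out = table.values.T.groupby(groups, sort=False).sum(min_count=1).T
    result = table.with_values(out)
    _log_dims("aggregate_taxa", table, result)
    return result


def filter_low_total(
    table: FeatureTable, min_total: float = 3, exclude: Sequence = ()
) -> FeatureTable:
    """Drop features whose column total over all samples is strictly below
    ``min_total``; ``exclude`` removes named features first (contaminants)."""
    values = table.values
    if exclude:
        present = [f for f in exclude if f in values.columns]
        absent = set(exclude) - set(present)
        if absent:
            warnings.warn(f"exclusion list names absent features: {sorted(absent)[:5]}")
        values = values.drop(columns=present)
    totals = values.sum(axis=0, skipna=True)
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        warnings.warn("filter_low_total removed every feature")
    result = table.with_values(values.loc[:, keep])
    _log_dims("filter_low_total", table, result)
    return result


def rclr(table: FeatureTable) -> FeatureTable:
    """Robust centered log-ratio transform.

    Each positive entry x in a sample row becomes ln(x) minus the mean of
    the natural logs of that row's positive entries.  Zeros (and missing
    entries) become missing in the output — no pseudocounts are added, so
    the transform is scale-invariant per row.
    """
    x = table.values.to_numpy(dtype=float)
    if x.size and np.nanmin(x) < 0:
        raise ValueError("rclr requires non-negative values")
    positive = (x > 0) & ~np.isnan(x)
    if not positive.any(axis=1).all():
        bad = [table.sample_ids[i] for i in np.where(~positive.any(axis=1))[0]]
        raise ValueError(f"rclr: sample(s) with no positive entries: {bad[:5]}")
    out = np.full_like(x, np.nan, dtype=float)
    logx = np.where(positive, np.log(np.where(positive, x, 1.0)), np.nan)
    row_mean = np.nanmean(logx, axis=1, keepdims=True)
    out[positive] = (logx - row_mean)[positive]
    result = table.with_values(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns)
    )
    _log_dims("rclr", table, result)
    return result


def lod_filter(table: FeatureTable, lod, max_frac: float = 0.2) -> FeatureTable:
    """Drop features below their limit of detection in more than
    ``max_frac`` of the samples (strict >).

    ``lod`` is a scalar or a per-feature mapping/Series.  Missing entries
    count as below the limit (not detected).
    """
    values = table.values
    if np.isscalar(lod):
        lod_s = pd.Series(float(lod), index=values.columns)
    else:
        lod_s = pd.Series(lod).reindex(values.columns)
        if lod_s.isna().any():
            missing = list(lod_s.index[lod_s.isna()])
            raise ValueError(f"no LOD given for features: {missing[:5]}")
    below = values.lt(lod_s, axis=1) | values.isna()
    frac = below.mean(axis=0)
    keep = frac.index[frac <= max_frac]
    result = table.with_values(values.loc[:, keep])
    _log_dims("lod_filter", table, result)
    return result


def missingness_filter(table: FeatureTable, max_frac: float = 0.2) -> FeatureTable:
    """Drop features with missing fraction strictly greater than ``max_frac``."""
    frac = table.values.isna().mean(axis=0)
    keep = frac.index[frac <= max_frac]
    result = table.with_values(table.values.loc[:, keep])
    _log_dims("missingness_filter", table, result)
    return result


def weight_normalize(table: FeatureTable, weights) -> FeatureTable:
    """Divide each sample row by its (positive) weight, e.g. dry sample weight."""
    if isinstance(weights, (pd.Series, dict)):
        w = pd.Series(weights).reindex(table.values.index)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=table.values.index)
    if w.isna().any():
        raise ValueError("missing weight for some samples")
    if (w <= 0).any():
        bad = list(w.index[w <= 0])
        raise ValueError(f"nonpositive weight for sample(s): {bad[:5]}")
    result = table.with_values(table.values.div(w, axis=0))
    _log_dims("weight_normalize", table, result)
    return result


def log2_transform(table: FeatureTable) -> FeatureTable:
    """log2 of every non-missing entry; nonpositive non-missing entries error."""
    values = table.values
    nonpos = (values <= 0) & values.notna()
    if nonpos.any().any():
        bad = [c for c in values.columns if nonpos[c].any()]
        raise ValueError(f"log2_transform: nonpositive values in feature(s): {bad[:5]}")
    result = table.with_values(np.log2(values))
    _log_dims("log2_transform", table, result)
    return result


def fit_censored_normal(
    observed, n_total: int, tail_quantile: float = 0.75
) -> tuple[float, float]:
    """Fit a normal to left-censored data from its observed upper tail.

    ``observed`` are the non-missing values of one feature; the feature had
    ``n_total`` samples in total, so the ``n_total - len(observed)`` missing
    ones are assumed censored below every observed value.  The observed
    order statistics are regressed on standard-normal quantiles computed at
    censoring-aware plotting positions, restricted to the upper
    ``tail_quantile`` fraction of the observed points.  Returns (mean, sd).
    """
    obs = np.sort(np.asarray(observed, dtype=float))
    n_obs = obs.size
    if n_obs < 3:
        raise ValueError("need at least 3 observed values")
    n_missing = n_total - n_obs
    if n_missing < 0:
        raise ValueError("n_total smaller than number of observed values")
    ranks = n_missing + np.arange(1, n_obs + 1)
    p = (ranks - 0.5) / n_total
    z = stats.norm.ppf(p)
    start = int(np.floor(n_obs * (1.0 - tail_quantile)))
    z_fit, x_fit = z[start:], obs[start:]
    slope, intercept, *_ = stats.linregress(z_fit, x_fit)
    if not np.isfinite(slope) or slope <= 0:
        slope = float(np.std(obs, ddof=1)) or 1.0
    return float(intercept), float(slope)


def qrilc_impute(
    table: FeatureTable,
    tail_quantile: float = 0.75,
    seed: int | None = None,
) -> FeatureTable:
    """Quantile-regression imputation of left-censored missing values.

    Per feature, a normal distribution is fitted to the observed upper tail
    (see :func:`fit_censored_normal`) and each missing entry is replaced by
    a draw from that normal truncated above at the feature's observed
    minimum.  Features with fewer than 3 observed values fall back to a fit
    pooled over the whole table (with a warning).  Input is expected on the
    log scale.  Reproducible given ``seed``.
    """
    if not (0 < tail_quantile <= 1):
        raise ValueError("tail_quantile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    n = len(values)
    if not values.isna().any().any():
        return table.with_values(values)

    pooled = values.to_numpy(dtype=float).ravel()
    pooled_obs = pooled[~np.isnan(pooled)]
    global_fit: tuple[float, float] | None = None

    for col in values.columns:
        x = values[col]
        miss = x.isna()
        if not miss.any():
            continue
        obs = x.dropna().to_numpy()
        if obs.size >= 3:
            mu, sd = fit_censored_normal(obs, n, tail_quantile)
        else:
            if global_fit is None:
                global_fit = fit_censored_normal(pooled_obs, pooled.size, tail_quantile)
            mu, sd = global_fit
            warnings.warn(
                f"qrilc_impute: feature {col!r} has <3 observed values; using global fit"
            )
        upper = float(np.min(obs)) if obs.size else mu
        sd = max(sd, 1e-12)
        b = (upper - mu) / sd
        draws = stats.truncnorm.rvs(
            -np.inf, b, loc=mu, scale=sd, size=int(miss.sum()), random_state=rng
        )
        values.loc[miss, col] = draws
    result = table.with_values(values)
    _log_dims("qrilc_impute", table, result)
    return result


def nzv_keep(
    table: FeatureTable, freq_cut: float = 19.0, unique_cut: float = 0.1
) -> list:
    """Feature ids surviving the near-zero-variance rule.

    A feature is dropped if it is constant, or if the frequency ratio of
    its two most common values is >= ``freq_cut`` while its fraction of
    unique values is < ``unique_cut``.
    """
    keep = []
    n = table.n_samples
    for col in table.values.columns:
        x = table.values[col].dropna()
        counts = x.value_counts()
        if len(counts) < 2:
            continue  # constant (or all-missing) column
        ratio = counts.iloc[0] / counts.iloc[1]
        unique_frac = len(counts) / n
        if ratio >= freq_cut and unique_frac < unique_cut:
            continue
        keep.append(col)
    return keep


def nzv_filter(
    table: FeatureTable, freq_cut: float = 19.0, unique_cut: float = 0.1
) -> FeatureTable:
    result = table.select_features(nzv_keep(table, freq_cut, unique_cut))
    _log_dims("nzv_filter", table, result)
    return result


def correlation_keep(table: FeatureTable, cutoff: float = 0.9) -> list:
    """Feature ids surviving greedy decorrelation.

    Repeatedly find the pair with the highest absolute Pearson correlation
    above ``cutoff`` and drop the member with the larger mean absolute
    correlation to all remaining features.
    """
    corr = table.values.corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)
    while True:
        flat = corr.values
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        if flat[i, j] <= cutoff:
            break
        mean_i = corr.iloc[i].mean()
        mean_j = corr.iloc[j].mean()
        drop = corr.index[i] if mean_i >= mean_j else corr.index[j]
        corr = corr.drop(index=drop, columns=drop)
        if corr.shape[0] < 2:
            break
    return [f for f in table.feature_ids if f in set(corr.index)]


def correlation_filter(table: FeatureTable, cutoff: float = 0.9) -> FeatureTable:
    result = table.select_features(correlation_keep(table, cutoff))
    _log_dims("correlation_filter", table, result)
    return result


# ---------------------------------------------------------------------------
# Recipes: ordered, parameterized transform lists (view manifest entries)
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "aggregate_taxa": aggregate_taxa,
    "filter_low_total": filter_low_total,
    "rclr": rclr,
    "lod_filter": lod_filter,
    "missingness_filter": missingness_filter,
    "weight_normalize": weight_normalize,
    "log2_transform": log2_transform,
    "qrilc_impute": qrilc_impute,
    "nzv_filter": nzv_filter,
    "correlation_filter": correlation_filter,
}


def apply_recipe(table: FeatureTable, steps, seed: int | None = None) -> FeatureTable:
    """Apply an ordered list of transform steps.

    ``steps`` is a list of step names or ``{"name": ..., "params": {...}}``
    dicts (the YAML manifest form).  ``seed`` is forwarded to stochastic
    steps that do not set their own.
    """
    for step in steps:
        if isinstance(step, str):
            name, params = step, {}
        else:
            name, params = step["name"], dict(step.get("params", {}))
        if name not in _TRANSFORMS:
            raise KeyError(f"unknown transform {name!r}")
        if name == "qrilc_impute" and "seed" not in params:
            params["seed"] = seed
        table = _TRANSFORMS[name](table, **params)
    return table


def default_recipe(modality: str) -> list:
    """Default preprocessing steps per modality."""
    if modality in ("counts", "intensity"):
        return [
            {"name": "filter_low_total", "params": {"min_total": 3}},
            {"name": "rclr", "params": {}},
        ]
    if modality == "metabolite":
        return [
            {"name": "missingness_filter", "params": {"max_frac": 0.2}},
            {"name": "qrilc_impute", "params": {}},
        ]
    # npx values are already on a log scale; clinical needs no transform
    return []
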