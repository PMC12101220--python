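"""Late integration: AUC-proportional weighting of per-view classifiers,
threshold selection, and the early-integration comparator (view
concatenation)."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .learner import ViewModel, predict_proba
from .metrics import geometric_mean, sens_spec

__all__ = [
    "compute_weights",
    "combine",
    "select_threshold",
    "default_threshold_grid",
    "classify",
    "concatenate_views",
    "EnsembleModel",
]


def compute_weights(train_aucs):
    """Normalize per-view training AUCs into weights: W_i = AUC_i / sum AUC_j.

    Accepts a sequence or a mapping; returns the same container kind.
    """
    if isinstance(train_aucs, Mapping):
        keys = list(train_aucs)
        vals = np.asarray([train_aucs[k] for k in keys], dtype=float)
    else:
        keys = None
        vals = np.asarray(list(train_aucs), dtype=float)
    if vals.size == 0:
        raise ValueError("no AUCs given")
    if (vals <= 0).any() or np.isnan(vals).any():
        raise ValueError("all AUCs must be positive")
    w = vals / vals.sum()
    if keys is not None:
        return dict(zip(keys, w.tolist()))
    return w


def combine(weights: Mapping[str, float], probs: pd.DataFrame) -> pd.Series:
    """Weighted sum of per-view probabilities, renormalized over the views
    available for each sample.

    ``probs`` has one column per view (NaN where a view lacks the sample).
    A sample missing from every view is an error.
    """
    missing_views = [v for v in weights if v not in probs.columns]
    if missing_views:
        raise KeyError(f"probability columns missing for views: {missing_views}")
    cols = list(weights)
    p = probs.loc[:, cols]
    w = np.asarray([weights[v] for v in cols], dtype=float)
    avail = p.notna().to_numpy()
    if not avail.any(axis=1).all():
        bad = list(p.index[~avail.any(axis=1)])
        raise ValueError(f"sample(s) absent from every view: {bad[:5]}")
    weighted = np.where(avail, p.to_numpy(dtype=float) * w, 0.0).sum(axis=1)
    denom = (avail * w).sum(axis=1)
    return pd.Series(weighted / denom, index=p.index)


def default_threshold_grid() -> np.ndarray:
    """Candidate decision thresholds: 0.05 to 0.95 in steps of 0.01."""
    return np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 2)


def select_threshold(
    oof_probs: Mapping[str, pd.Series],
    labels: Mapping[str, Sequence] | Sequence,
    grid: Sequence[float] | None = None,
    per_view_mean: bool = False,
) -> float:
    """Pick the decision threshold maximizing the geometric mean of all
    views' training sensitivities and specificities.

    By default the 2V per-view sensitivities and specificities are pooled
    into a single geometric mean per threshold; ``per_view_mean=True``
    instead averages per-view geometric means.  Ties are broken toward the
    threshold closest to 0.5, then the smaller one.  If every candidate
    scores zero the default 0.5 is returned with a warning.
    """
    if grid is None:
        grid = default_threshold_grid()
    views = list(oof_probs)
    if not views:
        raise ValueError("no views given")
    if not isinstance(labels, Mapping):
        labels = {v: labels for v in views}

    best_t, best_score = None, -np.inf
    for t in grid:
        parts = []
        for v in views:
            sens, spec = sens_spec(labels[v], oof_probs[v], t)
            parts.append((sens, spec))
        if per_view_mean:
            score = float(np.mean([geometric_mean(p) for p in parts]))
        else:
            score = geometric_mean([x for p in parts for x in p])
        better = score > best_score + 1e-12
        tie = abs(score - best_score) <= 1e-12
        if better or (
            tie
            and (
                abs(t - 0.5) < abs(best_t - 0.5) - 1e-12
                or (abs(abs(t - 0.5) - abs(best_t - 0.5)) <= 1e-12 and t < best_t)
            )
        ):
            best_t, best_score = float(t), score
    if best_score <= 0.0:
        warnings.warn("all candidate thresholds scored zero; falling back to 0.5")
        return 0.5
    return best_t


def classify(probs, threshold: float) -> np.ndarray:
    """Hard labels from combined probabilities: positive iff p >= threshold."""
    return (np.asarray(probs, dtype=float) >= threshold).astype(int)


def concatenate_views(tables: Sequence[FeatureTable], modality: str = "concat") -> FeatureTable:
    """Column-wise concatenation with view-prefixed feature ids
    (early-integration input).  Sample sets are inner-joined with a warning
    when they differ."""
    if not tables:
        raise ValueError("no tables to concatenate")
    common = tables[0].values.index
    for t in tables[1:]:
        common = common.intersection(t.values.index)
    if any(len(t.values.index) != len(common) for t in tables):
        warnings.warn("concatenate_views: sample sets differ; taking inner join")
    if len(common) == 0:
        raise ValueError("concatenate_views: no common samples")
    parts = []
    for i, t in enumerate(tables):
        prefix = t.name or f"view{i}"
        block = t.values.loc[common]
        block = block.rename(
            columns={c: c if str(c).startswith(f"{prefix}:") else f"{prefix}:{c}" for c in block.columns}
        )
        parts.append(block)
    merged = pd.concat(parts, axis=1)
    if merged.columns.has_duplicates:
        raise ValueError("concatenate_views produced duplicate feature ids")
    return FeatureTable(values=merged, modality=modality, name="concat")


@dataclass
class EnsembleModel:
    """A set of per-view models with normalized AUC weights and a threshold."""

    models: dict[str, ViewModel] = field(repr=False)
    weights: dict[str, float]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if set(self.models) != set(self.weights):
            raise ValueError("weights must cover exactly the ensemble's views")
        w = np.asarray(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @property
    def view_names(self) -> list[str]:
        return list(self.models)

    def predict_views(self, tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        """Per-view positive-class probabilities (NaN for absent samples)."""
        cols = {}
        index = None
        for v, model in self.models.items():
            if v not in tables:
                raise KeyError(f"no table for ensemble view {v!r}")
            s = predict_proba(model, tables[v])
            cols[v] = s
            index = s.index if index is None else index.union(s.index)
        return pd.DataFrame({v: s.reindex(index) for v, s in cols.items()})

    def predict_proba(self, tables: Mapping[str, pd.DataFrame]) -> pd.Series:
        return combine(self.weights, self.predict_views(tables))

    def predict(self, tables: Mapping[str, pd.DataFrame]) -> pd.Series:
        p = self.predict_proba(tables)
        return pd.Series(classify(p, self.threshold), index=p.index)

    # -- persistence (metadata only; forests are refittable from config) ----
    def meta_json(self, path: str | Path | None = None) -> str:
        payload = {
            "views": [
                {
                    "name": v,
                    "mtry": m.mtry,
                    "ntree": m.ntree,
                    "train_auc": m.train_auc,
                    "weight": self.weights[v],
                    "n_features": len(m.features),
                    "seed": m.seed,
                }
                for v, m in self.models.items()
            ],
            "threshold": self.threshold,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
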