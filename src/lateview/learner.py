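"""Per-view random-forest learners with grouped-CV hyperparameter tuning.

The base learner is a random forest preceded by a median-imputation shim
(fit on the training folds only) so views whose transforms leave missing
values — e.g. the robust CLR — still yield complete input for the trees.
The stored ``train_auc`` is always computed from pooled out-of-fold
predictions, never from resubstitution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.pipeline import Pipeline

from .metrics import auc

__all__ = ["ViewModel", "default_hyperparams", "tune_and_train", "predict_proba"]


def default_hyperparams(n_features: int) -> tuple[int, int]:
    """Default forest settings: mtry = floor(sqrt(p)), ntree = 500."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, int(math.floor(math.sqrt(n_features)))), 500


def default_mtry_grid(n_features: int) -> list[int]:
    """mtry candidates at {0.5, 1, 2} x floor(sqrt(p)), clamped to [1, p]."""
    base, _ = default_hyperparams(n_features)
    grid = sorted({int(np.clip(m, 1, n_features)) for m in (base // 2, base, 2 * base)})
    return [m for m in grid if m >= 1]


@dataclass
class ViewModel:
    """A fitted per-view classifier plus its tuning record."""

    name: str
    estimator: Pipeline = field(repr=False)
    mtry: int
    ntree: int
    train_auc: float
    features: list
    oof_proba: pd.Series = field(repr=False)  # pooled out-of-fold train probabilities
    oof_labels: pd.Series = field(repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.mtry <= len(self.features)):
            raise ValueError("mtry outside [1, n_features]")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if not (0.0 <= self.train_auc <= 1.0):
            raise ValueError("train_auc outside [0, 1]")


def _make_pipeline(mtry: int, ntree: int, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            (
                "forest",
                RandomForestClassifier(
                    n_estimators=ntree,
                    max_features=mtry,
                    random_state=seed,
                    n_jobs=1,
                ),
            ),
        ]
    )


def _positive_proba(pipe: Pipeline, x: np.ndarray) -> np.ndarray:
    forest = pipe.named_steps["forest"]
    classes = list(forest.classes_)
    if 1 not in classes:
        raise ValueError("model was trained without the positive class")
    return pipe.predict_proba(x)[:, classes.index(1)]


def _oof_probabilities(
    x: np.ndarray, y: np.ndarray, fold_ids: np.ndarray, mtry: int, ntree: int, seed: int
) -> np.ndarray:
    """Pooled out-of-fold probabilities for one hyperparameter point."""
    oof = np.full(len(y), np.nan)
    for f in np.unique(fold_ids):
        held = fold_ids == f
        y_tr = y[~held]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"CV fold {int(f)}: training partition has a single class")
        pipe = _make_pipeline(mtry, ntree, seed)
        pipe.fit(x[~held], y_tr)
        oof[held] = _positive_proba(pipe, x[held])
    return oof


def tune_and_train(
    name: str,
    table: pd.DataFrame,
    labels,
    fold_ids,
    mtry_grid: Sequence[int] | None = None,
    ntree_grid: Sequence[int] | None = None,
    seed: int = 0,
) -> ViewModel:
    """Grid-search (mtry, ntree) by pooled out-of-fold AUC, then refit.

    Ties are broken toward the smaller mtry, then the smaller ntree.  The
    winning grid point's out-of-fold AUC is stored as ``train_auc`` and its
    out-of-fold probabilities are kept for downstream threshold selection.
    """
    x = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    folds = np.asarray(fold_ids)
    if len(y) != len(x) or len(folds) != len(x):
        raise ValueError("labels/folds length mismatch with table")
    p = table.shape[1]
    if mtry_grid is None:
        mtry_grid = default_mtry_grid(p)
    if ntree_grid is None:
        ntree_grid = [500, 1000]

    best = None  # (auc, mtry, ntree, oof)
    for mtry in sorted(mtry_grid):
        if not (1 <= mtry <= p):
            raise ValueError(f"mtry {mtry} outside [1, {p}]")
        for ntree in sorted(ntree_grid):
            oof = _oof_probabilities(x, y, folds, mtry, ntree, seed)
            score = auc(y, oof)
            if best is None or score > best[0]:
                best = (score, mtry, ntree, oof)
    score, mtry, ntree, oof = best

    pipe = _make_pipeline(mtry, ntree, seed)
    pipe.fit(x, y)
    return ViewModel(
        name=name,
        estimator=pipe,
        mtry=mtry,
        ntree=ntree,
        train_auc=score,
        features=list(table.columns),
        oof_proba=pd.Series(oof, index=table.index),
        oof_labels=pd.Series(y, index=table.index),
        seed=seed,
    )


def predict_proba(model: ViewModel, table: pd.DataFrame) -> pd.Series:
    """Probability of the positive (persistent) class per sample."""
    missing = [f for f in model.features if f not in table.columns]
    if missing:
        raise KeyError(f"table lacks model features: {missing[:5]}")
    x = table.loc[:, model.features].to_numpy(dtype=float)
    return pd.Series(_positive_proba(model.estimator, x), index=table.index)
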