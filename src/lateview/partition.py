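"""Grouped, stratified data partitioning and class-imbalance resampling.

All splitting is done at the subject level so that repeated measurements
(visits) of one subject never straddle a train/test boundary or a CV fold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import CohortMeta

__all__ = [
    "RepeatSplit",
    "SplitPlan",
    "grouped_stratified_split",
    "grouped_stratified_kfold",
    "random_oversample",
    "smote",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class RepeatSplit:
    train: list
    test: list
    folds: dict  # subject -> fold index in [0, k)


@dataclass
class SplitPlan:
    """Repeated grouped stratified train/test splits plus CV fold maps."""

    repeats: list[RepeatSplit]
    seed: int
    k: int = 5

    def __post_init__(self) -> None:
        for r, rep in enumerate(self.repeats):
            if set(rep.train) & set(rep.test):
                raise ValueError(f"repeat {r}: train/test overlap")
            if rep.folds and set(rep.folds) != set(rep.train):
                raise ValueError(f"repeat {r}: fold map does not cover the training set")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "k": self.k,
            "repeats": [
                {"train": list(r.train), "test": list(r.test), "folds": dict(r.folds)}
                for r in self.repeats
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        repeats = [
            RepeatSplit(r["train"], r["test"], r["folds"]) for r in payload["repeats"]
        ]
        return cls(repeats=repeats, seed=payload["seed"], k=payload.get("k", 5))


def grouped_stratified_kfold(
    outcomes: Mapping | pd.Series, k: int = 5, seed: int | None = None, rng=None
) -> dict:
    """Assign subjects to k CV folds, stratified by outcome.

    Per class, fold counts differ by at most one; larger per-class chunks
    are placed on the currently smallest folds so overall fold sizes are as
    balanced as possible.
    """
    outcomes = pd.Series(outcomes)
    if rng is None:
        rng = np.random.default_rng(seed)
    fold_of: dict = {}
    fold_totals = np.zeros(k, dtype=int)
    classes = sorted(outcomes.unique(), key=lambda c: -int((outcomes == c).sum()))
    for cls in classes:
        subjects = list(outcomes.index[outcomes == cls])
        rng.shuffle(subjects)
        base, rem = divmod(len(subjects), k)
        sizes = sorted([base + 1] * rem + [base] * (k - rem), reverse=True)
        order = np.argsort(fold_totals, kind="stable")
        pos = 0
        for fold, size in zip(order, sizes):
            for s in subjects[pos : pos + size]:
                fold_of[s] = int(fold)
            fold_totals[fold] += size
            pos += size
    return fold_of


def grouped_stratified_split(
    meta: CohortMeta,
    train_frac: float = 2 / 3,
    n_repeats: int = 5,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Repeated subject-level stratified train/test splits with CV folds.

    Per class, round(train_frac * class size) subjects (half-up) go to the
    training set; the largest class is then adjusted so the overall training
    size equals round(train_frac * n_subjects).  All visits of a subject
    follow the subject.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    outcomes = meta.subject_outcomes
    by_class = {c: list(outcomes.index[outcomes == c]) for c in sorted(outcomes.unique())}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c} has fewer than 2 subjects")

    n_train = {c: _round_half_up(train_frac * len(m)) for c, m in by_class.items()}
    target = _round_half_up(train_frac * meta.n_subjects)
    diff = target - sum(n_train.values())
    if diff:
        largest = max(by_class, key=lambda c: len(by_class[c]))
        n_train[largest] = int(
            np.clip(n_train[largest] + diff, 1, len(by_class[largest]) - 1)
        )
    for c in by_class:
        n_train[c] = int(np.clip(n_train[c], 1, len(by_class[c]) - 1))

    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        train: list = []
        for c, members in by_class.items():
            chosen = rng.choice(len(members), size=n_train[c], replace=False)
            train.extend(members[i] for i in sorted(chosen))
        train_set = set(train)
        test = [s for s in outcomes.index if s not in train_set]
        folds = grouped_stratified_kfold(outcomes.loc[train], k=k, rng=rng)
        repeats.append(RepeatSplit(train=train, test=test, folds=folds))
    return SplitPlan(repeats=repeats, seed=seed, k=k)


def random_oversample(
    table: pd.DataFrame, labels, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Duplicate minority-class rows (sampling with replacement) until the
    class counts are equal.  Balanced input is returned unchanged."""
    y = np.asarray(labels)
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValueError("random_oversample expects exactly two classes")
    if counts[0] == counts[1]:
        return table.copy(), y.copy()
    minority = values[np.argmin(counts)]
    n_extra = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)
    minority_pos = np.where(y == minority)[0]
    extra = rng.choice(minority_pos, size=n_extra, replace=True)
    out = pd.concat([table, table.iloc[extra]], axis=0)
    out_y = np.concatenate([y, y[extra]])
    return out, out_y


def smote(
    table: pd.DataFrame,
    labels,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic minority oversampling by interpolation between minority
    nearest neighbours, until the classes balance.

    Raises ``ValueError`` when the minority class has too few samples
    (size <= k_neighbors) to define the neighbourhoods.
    """
    y = np.asarray(labels)
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ValueError("smote expects exactly two classes")
    if table.isna().any().any():
        raise ValueError("smote requires a complete (imputed) table")
    minority = values[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k_neighbors:
        raise ValueError(
            f"insufficient minority samples for SMOTE: minority size {n_min} "
            f"<= k_neighbors {k_neighbors}"
        )
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return table.copy(), y.copy()
    x_min = table.to_numpy(dtype=float)[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)  # first neighbour is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    neighbours = idx[base, pick]
    synthetic = x_min[base] + lam[:, None] * (x_min[neighbours] - x_min[base])
    synth_df = pd.DataFrame(
        synthetic,
        columns=table.columns,
        index=[f"smote_{i}" for i in range(n_new)],
    )
    out = pd.concat([table, synth_df], axis=0)
    out_y = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return out, out_y
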