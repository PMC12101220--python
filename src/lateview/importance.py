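"""Variable importance for the final ensemble.

Two complementary measures: impurity (Gini) importance read off each fitted
forest (training side), and permutation importance — the mean decrease in
combined test AUC when one feature's test-set values are shuffled —
aggregated across the repeated train/test splits.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .integrate import EnsembleModel, combine
from .learner import ViewModel
from .metrics import auc

__all__ = [
    "permutation_importance",
    "gini_importance",
    "aggregate_importance",
    "IMPORTANCE_CUTOFF",
]

#: a feature is "important" when its grand-mean decrease in test AUC exceeds this
IMPORTANCE_CUTOFF = 0.01


def permutation_importance(
    ensemble: EnsembleModel,
    test_tables: Mapping[str, pd.DataFrame],
    labels,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean decrease in combined test AUC per shuffled feature.

    For every feature of every view in the ensemble, the feature's column in
    a copy of that view's test table is permuted (within the test set,
    without replacement), the view's probabilities are recomputed, and the
    combined AUC is compared against the unshuffled baseline.  Repeated
    ``n_perm`` times; the mean and standard deviation of the decrease are
    reported.  Features of views outside the ensemble are not touched.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    labels = pd.Series(labels)

    base_views = ensemble.predict_views(test_tables)
    baseline_probs = combine(ensemble.weights, base_views)
    index = baseline_probs.index
    y = labels.reindex(index).to_numpy()
    baseline = auc(y, baseline_probs.to_numpy())

    # precompute the weighted-sum decomposition so each shuffle only has to
    # swap one view's contribution in and out (weights are fixed)
    w = np.asarray([ensemble.weights[v] for v in base_views.columns])
    avail = base_views.notna().to_numpy()
    contrib = np.where(avail, base_views.to_numpy(dtype=float) * w, 0.0)
    total_num = contrib.sum(axis=1)
    denom = (avail * w).sum(axis=1)

    rows = []
    for vi, (view, model) in enumerate(ensemble.models.items()):
        table = test_tables[view].loc[:, model.features]
        n = len(table)
        x = table.to_numpy(dtype=float)
        positions = index.get_indexer(table.index)
        others_num = total_num - contrib[:, vi]
        w_v = ensemble.weights[view]
        pipe = model.estimator
        forest = pipe.named_steps["forest"]
        pos_col = list(forest.classes_).index(1)
        for j, feat in enumerate(model.features):
            decreases = np.empty(n_perm)
            work = x.copy()
            col = x[:, j].copy()
            for b in range(n_perm):
                work[:, j] = col[rng.permutation(n)]
                p_view = pipe.predict_proba(work)[:, pos_col]
                num = others_num.copy()
                num[positions] += w_v * p_view
                decreases[b] = baseline - auc(y, num / denom)
            rows.append(
                {
                    "view": view,
                    "feature": feat,
                    "mean_decrease": float(decreases.mean()),
                    "sd": float(decreases.std(ddof=1)),
                    "baseline_auc": baseline,
                    "n_perm": n_perm,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values("mean_decrease", ascending=False, ignore_index=True)


def gini_importance(model: ViewModel) -> pd.Series:
    """Impurity-based (Gini) importance of the fitted forest, per feature."""
    forest = model.estimator.named_steps["forest"]
    return pd.Series(forest.feature_importances_, index=model.features).sort_values(
        ascending=False
    )


def aggregate_importance(
    records: pd.DataFrame,
    n_repeats: int | None = None,
    cutoff: float = IMPORTANCE_CUTOFF,
) -> pd.DataFrame:
    """Grand-mean importance across repeats with the >cutoff importance flag.

    ``records`` concatenates per-repeat :func:`permutation_importance`
    outputs with a ``repeat`` column.  A (view, feature) absent from a
    repeat (its view was not selected there) contributes 0 for that repeat.
    """
    if "repeat" not in records.columns:
        raise ValueError("records need a 'repeat' column")
    if n_repeats is None:
        n_repeats = records["repeat"].nunique()
    wide = records.pivot_table(
        index=["view", "feature"], columns="repeat", values="mean_decrease"
    )
    grand = wide.fillna(0.0).sum(axis=1) / n_repeats
    sd = wide.fillna(0.0).std(axis=1, ddof=1) if wide.shape[1] > 1 else 0.0
    out = pd.DataFrame(
        {
            "grand_mean": grand,
            "sd_across_repeats": sd,
            "n_repeats_measured": wide.notna().sum(axis=1),
            "important": grand > cutoff,
        }
    ).reset_index()
    return out.sort_values("grand_mean", ascending=False, ignore_index=True)
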