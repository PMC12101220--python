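"""Greedy forward selection of the best view combination, plus the
subset-count bookkeeping that motivates it over exhaustive search."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .integrate import combine, compute_weights
from .metrics import auc

__all__ = ["ForwardSelectionResult", "forward_select", "count_combinations"]


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    trace: pd.DataFrame  # step, candidate, auc_before, auc_after, kept
    used_all_views: bool

    @property
    def auc_trace(self) -> list[float]:
        return list(self.trace["auc_after"][self.trace["kept"]])

    @property
    def final_auc(self) -> float:
        kept = self.trace[self.trace["kept"]]
        return float(kept["auc_after"].iloc[-1])


def _subset_auc(
    views: Sequence[str],
    test_probs: Mapping[str, pd.Series],
    train_aucs: Mapping[str, float],
    labels: pd.Series,
) -> float:
    weights = compute_weights({v: train_aucs[v] for v in views})
    frame = pd.DataFrame({v: test_probs[v] for v in views})
    combined = combine(weights, frame)
    return auc(labels.reindex(combined.index), combined)


def forward_select(
    test_probs: Mapping[str, pd.Series],
    train_aucs: Mapping[str, float],
    labels: pd.Series,
) -> ForwardSelectionResult:
    """Select the view subset by the greedy forward rule.

    If the all-views ensemble's test AUC is at least as high as every single
    view's, all views are kept.  Otherwise selection is seeded with the best
    single view (ties resolved by input order) and the remaining views are
    visited in descending individual test AUC; a candidate is kept iff
    adding it strictly increases the combined test AUC, with the AUC
    weights renormalized over the current subset at every step.
    """
    views = list(test_probs)
    if not views:
        raise ValueError("no views to select from")
    labels = pd.Series(labels)

    single = {v: auc(labels.reindex(test_probs[v].index), test_probs[v]) for v in views}
    all_auc = _subset_auc(views, test_probs, train_aucs, labels)

    rows = []
    if all_auc >= max(single.values()):
        rows.append(
            {"step": 0, "candidate": "+".join(views), "auc_before": np.nan,
             "auc_after": all_auc, "kept": True}
        )
        return ForwardSelectionResult(
            selected=views, trace=pd.DataFrame(rows), used_all_views=True
        )

    best_view = max(views, key=lambda v: (single[v], -views.index(v)))
    selected = [best_view]
    current = single[best_view]
    rows.append(
        {"step": 0, "candidate": best_view, "auc_before": np.nan,
         "auc_after": current, "kept": True}
    )
    remaining = sorted(
        (v for v in views if v != best_view),
        key=lambda v: (-single[v], views.index(v)),
    )
    for step, cand in enumerate(remaining, start=1):
        trial = _subset_auc(selected + [cand], test_probs, train_aucs, labels)
        kept = trial > current  # strict improvement rule
        rows.append(
            {"step": step, "candidate": cand, "auc_before": current,
             "auc_after": trial, "kept": kept}
        )
        if kept:
            selected.append(cand)
            current = trial
    return ForwardSelectionResult(
        selected=selected, trace=pd.DataFrame(rows), used_all_views=False
    )


def count_combinations(view_counts: Sequence[int]) -> int:
    """Total non-empty view subsets summed over approaches:
    sum_k (2^n_k - 1)."""
    counts = list(view_counts)
    if not counts:
        raise ValueError("no view counts given")
    if any(int(n) != n or n < 0 for n in counts):
        raise ValueError("view counts must be non-negative integers")
    return int(sum(2 ** int(n) - 1 for n in counts))
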