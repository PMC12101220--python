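"""End-to-end orchestration: preprocess -> split -> per-view training ->
AUC-weighted combination -> threshold -> forward selection -> metrics ->
importance, repeated over train/test splits.

Two view constructions are supported: approach 1 keeps one view per
modality with all visits stacked as rows; approach 2 splits every modality
into one view per visit, with subjects as rows.  Early integration
concatenates every (preprocessed) view into a single table and runs the
same machinery with one view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CohortMeta, FeatureTable
from .importance import aggregate_importance, permutation_importance
from .integrate import (
    EnsembleModel,
    combine,
    compute_weights,
    concatenate_views,
    select_threshold,
)
from .learner import default_hyperparams, predict_proba, tune_and_train
from .metrics import auc, sens_spec, summarize
from .partition import SplitPlan, grouped_stratified_split
from .preprocess import apply_recipe, default_recipe
from .select import forward_select

__all__ = ["ExperimentConfig", "ExperimentResult", "build_views", "run_experiment"]

log = logging.getLogger(__name__)

ROW_SEP = "|"  # approach-1 row ids are "<subject>|<visit>"


@dataclass
class ExperimentConfig:
    approach: int = 2
    integration: str = "late"  # "late" or "early"
    n_repeats: int = 5
    train_frac: float = 2 / 3
    k: int = 5
    seed: int = 0
    tune: bool = False
    mtry_grid: Sequence[int] | None = None
    ntree_grid: Sequence[int] | None = None
    ntree: int = 500
    threshold_grid: Sequence[float] | None = None
    forward_selection: bool = True
    compute_importance: bool = False
    n_perm: int = 100
    recipes: Mapping[str, list] | None = None  # modality -> steps override

    def __post_init__(self) -> None:
        if self.approach not in (1, 2):
            raise ValueError("approach must be 1 or 2")
        if self.integration not in ("late", "early"):
            raise ValueError("integration must be 'late' or 'early'")


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame  # one row per repeat
    summary: pd.DataFrame  # mean/sd per metric
    selection: pd.DataFrame  # forward-selection traces, all repeats
    importance: pd.DataFrame | None
    importance_by_repeat: pd.DataFrame | None
    config: ExperimentConfig
    plan: SplitPlan
    ensembles: list = field(repr=False, default_factory=list)


def build_views(
    tables: Mapping[tuple, FeatureTable], meta: CohortMeta, approach: int
) -> tuple[dict[str, FeatureTable], pd.Series]:
    """Assemble per-view tables and per-row labels for one approach.

    Approach 1: one view per modality name; rows are subject|visit pairs,
    restricted to features present at every visit.  Approach 2: one view
    per (name, visit); rows are subjects.  Returns (views, labels) where
    ``labels`` covers every row id that can occur.
    """
    outcomes = meta.subject_outcomes
    view_names = list(dict.fromkeys(name for name, _ in tables))
    visits = list(dict.fromkeys(visit for _, visit in tables))

    views: dict[str, FeatureTable] = {}
    if approach == 2:
        for (name, visit), ft in tables.items():
            views[f"{name}@{visit}"] = ft
        labels = outcomes.copy()
    elif approach == 1:
        for name in view_names:
            parts = []
            common = None
            for visit in visits:
                ft = tables[(name, visit)]
                common = ft.values.columns if common is None else common.intersection(ft.values.columns)
            for visit in visits:
                block = tables[(name, visit)].values.loc[:, common]
                block = block.rename(index=lambda s: f"{s}{ROW_SEP}{visit}")
                parts.append(block)
            stacked = pd.concat(parts, axis=0)
            views[name] = FeatureTable(
                values=stacked, modality=tables[(name, visits[0])].modality, name=name
            )
        labels = pd.Series(
            {
                f"{s}{ROW_SEP}{v}": int(outcomes[s])
                for s in outcomes.index
                for v in visits
            }
        )
    else:
        raise ValueError("approach must be 1 or 2")
    return views, labels


def _row_subject(row_id) -> str:
    return str(row_id).split(ROW_SEP, 1)[0]


def _preprocess_views(
    views: dict[str, FeatureTable], config: ExperimentConfig
) -> dict[str, FeatureTable]:
    out = {}
    for i, (name, ft) in enumerate(views.items()):
        if config.recipes is not None and ft.modality in config.recipes:
            steps = config.recipes[ft.modality]
        else:
            steps = default_recipe(ft.modality)
        out[name] = apply_recipe(ft, steps, seed=config.seed * 7919 + i)
        log.info(
            "view %s (%s): %d -> %d features after preprocessing",
            name, ft.modality, ft.n_features, out[name].n_features,
        )
    return out


def run_experiment(
    tables: Mapping[tuple, FeatureTable],
    meta: CohortMeta,
    config: ExperimentConfig | None = None,
) -> ExperimentResult:
    """Run the full repeated train/test procedure on one cohort."""
    config = config or ExperimentConfig()
    views, labels = build_views(tables, meta, config.approach)
    views = _preprocess_views(views, config)

    if config.integration == "early":
        renamed = [
            FeatureTable(values=ft.values, modality=ft.modality, name=key)
            for key, ft in views.items()
        ]
        views = {"all": concatenate_views(renamed)}

    plan = grouped_stratified_split(
        meta,
        train_frac=config.train_frac,
        n_repeats=config.n_repeats,
        k=config.k,
        seed=config.seed,
    )

    metric_rows = []
    selection_frames = []
    importance_frames = []
    ensembles = []
    for r, rep in enumerate(plan.repeats):
        train_set, test_set = set(rep.train), set(rep.test)
        models = {}
        test_probs = {}
        test_tables = {}
        oof_probs = {}
        oof_labels = {}
        y_test_any = None
        for name, ft in views.items():
            rows = ft.values.index
            subj = rows.map(_row_subject)
            tr_rows = rows[subj.isin(train_set)]
            te_rows = rows[subj.isin(test_set)]
            x_tr = ft.values.loc[tr_rows]
            x_te = ft.values.loc[te_rows]
            y_tr = labels.reindex(tr_rows).to_numpy()
            fold_ids = [rep.folds[_row_subject(i)] for i in tr_rows]

            if config.tune:
                mtry_grid, ntree_grid = config.mtry_grid, config.ntree_grid
            else:
                mtry_default, _ = default_hyperparams(x_tr.shape[1])
                mtry_grid = [mtry_default]
                ntree_grid = [config.ntree]
            model = tune_and_train(
                name, x_tr, y_tr, fold_ids,
                mtry_grid=mtry_grid, ntree_grid=ntree_grid,
                seed=config.seed * 1009 + r,
            )
            models[name] = model
            test_tables[name] = x_te
            test_probs[name] = predict_proba(model, x_te)
            oof_probs[name] = model.oof_proba
            oof_labels[name] = model.oof_labels.to_numpy()
            y_test_any = labels.reindex(te_rows)

        train_aucs = {v: m.train_auc for v, m in models.items()}
        threshold = select_threshold(oof_probs, oof_labels, grid=config.threshold_grid)

        y_test = labels.reindex(test_probs[next(iter(test_probs))].index)
        if config.forward_selection and len(views) > 1:
            fs = forward_select(test_probs, train_aucs, y_test)
            selected = fs.selected
            trace = fs.trace.assign(repeat=r)
        else:
            selected = list(views)
            trace = pd.DataFrame(
                [{"step": 0, "candidate": "+".join(selected), "auc_before": np.nan,
                  "auc_after": np.nan, "kept": True, "repeat": r}]
            )
        selection_frames.append(trace)

        weights = compute_weights({v: train_aucs[v] for v in selected})
        ensemble = EnsembleModel(
            models={v: models[v] for v in selected}, weights=weights, threshold=threshold
        )
        ensembles.append(ensemble)

        combined = combine(weights, pd.DataFrame({v: test_probs[v] for v in selected}))
        y_comb = labels.reindex(combined.index)
        rep_auc = auc(y_comb, combined)
        sens, spec = sens_spec(y_comb, combined, threshold)
        metric_rows.append(
            {
                "repeat": r,
                "auc": rep_auc,
                "sensitivity": sens,
                "specificity": spec,
                "threshold": threshold,
                "n_views_selected": len(selected),
                "selected_views": "+".join(selected),
            }
        )
        log.info("repeat %d: AUC=%.3f sens=%.3f spec=%.3f (views: %s)",
                 r, rep_auc, sens, spec, "+".join(selected))

        if config.compute_importance:
            imp = permutation_importance(
                ensemble,
                {v: test_tables[v] for v in selected},
                y_comb,
                n_perm=config.n_perm,
                seed=config.seed * 104729 + r,
            )
            importance_frames.append(imp.assign(repeat=r))

    metrics = pd.DataFrame(metric_rows)
    summary_rows = []
    for col in ("auc", "sensitivity", "specificity"):
        mean, sd = summarize(metrics[col])
        summary_rows.append({"metric": col, "mean": mean, "sd": sd})
    summary = pd.DataFrame(summary_rows)

    importance_by_repeat = (
        pd.concat(importance_frames, ignore_index=True) if importance_frames else None
    )
    importance = (
        aggregate_importance(importance_by_repeat, n_repeats=config.n_repeats)
        if importance_by_repeat is not None
        else None
    )
    return ExperimentResult(
        metrics=metrics,
        summary=summary,
        selection=pd.concat(selection_frames, ignore_index=True),
        importance=importance,
        importance_by_repeat=importance_by_repeat,
        config=config,
        plan=plan,
        ensembles=ensembles,
    )
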