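# lateview

Multi-view late-integration machine learning for small, multi-visit,
multi-omics cohorts. The package trains one random-forest classifier per
data view (a modality, optionally restricted to one visit), combines the
per-view predicted probabilities with AUC-proportional weights, tunes the
decision threshold on the geometric mean of training sensitivities and
specificities, greedily forward-selects the best view combination, and
reports permutation-based variable importance — all under repeated,
grouped, stratified train/test splitting that never separates the visits of
one subject.

A synthetic cohort generator emulates the data structure this kind of study
produces (compositional counts, zero-inflated intensities, log-scale
immune panels, left-censored metabolite tables, subject-level visit
correlation, a configurable informative-feature subset), so the full
pipeline is testable end to end without any external data.

## Layout

| Module | Purpose |
| --- | --- |
| `lateview.containers` | `FeatureTable` (samples x features with missing mask) and `CohortMeta` (subject, visit, outcome) |
| `lateview.synthetic` | multi-view, multi-visit cohort generator + cohort I/O |
| `lateview.preprocess` | genus aggregation, low-total filter, robust CLR, LOD/missingness filters, weight normalization, log2, QRILC imputation, NZV and correlation filters, recipe runner |
| `lateview.partition` | grouped stratified train/test splits and CV folds, random oversampling, SMOTE |
| `lateview.learner` | per-view random forest with median-impute shim, grouped-CV grid tuning of mtry/ntree, out-of-fold training AUC |
| `lateview.integrate` | AUC-proportional weights, weighted probability combination with renormalization, threshold selection, view concatenation (early integration), `EnsembleModel` |
| `lateview.select` | greedy forward selection of views, subset-count bookkeeping |
| `lateview.importance` | permutation importance (decrease in combined test AUC), Gini importance, cross-repeat aggregation |
| `lateview.metrics` | Mann–Whitney AUC, sensitivity/specificity, geometric mean, mean/sd summaries |
| `lateview.pipeline` | `run_experiment`: the full repeated end-to-end procedure (approach 1: one view per modality with visits stacked; approach 2: one view per modality x visit; late or early integration) |

## CLI

```bash
# 1. simulate a cohort (one CSV per view x visit, meta.csv, manifest.yaml)
lateview simulate --config cohort.yaml --out cohort/ --seed 7

# 2. optional: audit the split plan
lateview split --meta cohort/meta.csv --repeats 5 --seed 7 --out plan.json

# 3. fit the repeated multi-view experiment and write a bundle
lateview fit --data cohort/ --approach 2 --repeats 5 --seed 7 \
    --importance --out bundle/

# 4. print per-repeat metrics, summary and top importance
lateview report --bundle bundle/
```

A cohort config looks like:

```yaml
n_subjects: 39
n_positive: 15
visits: [baseline, 6M, 12M]
seed: 7
views:
  - {name: genus, modality: counts, n_features: 145, n_informative: 5,
     effect_size: 1.5, zero_frac: 0.3}
  - {name: immune, modality: npx, n_features: 58, n_informative: 5,
     effect_size: 1.5}
  - {name: metab_neg, modality: metabolite, n_features: 77, n_informative: 5,
     effect_size: 1.5, censor_frac: 0.15}
```

## Python API

```python
from lateview import CohortSpec, ViewSpec, generate_cohort
from lateview.pipeline import ExperimentConfig, run_experiment

tables, meta = generate_cohort(CohortSpec(
    n_subjects=39, n_positive=15, visits=["baseline", "6M", "12M"],
    view_specs=[ViewSpec("immune", "npx", 58, n_informative=5, effect_size=1.5)],
    seed=7,
))
result = run_experiment(tables, meta, ExperimentConfig(approach=2, seed=7))
print(result.summary)        # mean/sd of AUC, sensitivity, specificity
print(result.selection)      # forward-selection trace per repeat
```

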