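"""Synthetic multi-view, multi-visit cohort generator.

Emulates the statistical structure the downstream pipeline assumes: small
two-class cohorts observed at several visits, with compositional count
views, zero-inflated intensity views, log-scale Gaussian views, and
left-censored metabolite views.  A per-subject latent effect shared across
visits induces within-subject correlation, and a configurable subset of
informative features carries a class mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import KNOWN_MODALITIES, CohortMeta, FeatureTable

__all__ = ["ViewSpec", "CohortSpec", "generate_cohort", "write_cohort", "load_cohort"]

DEFAULT_VISITS = ("baseline", "6M", "12M")

#: loading of the per-(subject, visit) latent effect on each feature
_LATENT_LOADING = 0.6
#: scale of the latent effect on count log-concentrations
_LATENT_LOADING_COUNTS = 0.3


@dataclass
class ViewSpec:
    """Shape and signal parameters of one synthetic view."""

    name: str
    modality: str
    n_features: int
    n_informative: int = 0
    effect_size: float = 0.0
    zero_frac: float = 0.0
    censor_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in KNOWN_MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {KNOWN_MODALITIES}"
            )
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not (0 <= self.n_informative <= self.n_features):
            raise ValueError("n_informative must be in [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.zero_frac < 1):
            raise ValueError("zero_frac must be in [0, 1)")
        if not (0 <= self.censor_frac < 1):
            raise ValueError("censor_frac must be in [0, 1)")

    def feature_ids(self) -> list[str]:
        return [f"{self.name}:f{i:03d}" for i in range(self.n_features)]

    def informative_ids(self) -> list[str]:
        """Ids of the informative features (the first ``n_informative``)."""
        return self.feature_ids()[: self.n_informative]


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort."""

    n_subjects: int
    n_positive: int
    view_specs: Sequence[ViewSpec]
    visits: Sequence[str] = DEFAULT_VISITS
    subject_corr: float = 0.5
    seed: int = 0
    depth: int = 10_000
    visit_effect_multipliers: Sequence[float] | None = None
    missing_cells: Sequence[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.n_positive < self.n_subjects):
            raise ValueError("need 0 < n_positive < n_subjects")
        if not (0.0 <= self.subject_corr <= 1.0):
            raise ValueError("subject_corr must be in [0, 1]")
        if not self.view_specs:
            raise ValueError("at least one view spec required")
        if self.visit_effect_multipliers is None:
            self.visit_effect_multipliers = tuple(1.0 for _ in self.visits)
        if len(self.visit_effect_multipliers) != len(self.visits):
            raise ValueError("one effect multiplier per visit required")


def _continuous_block(rng, view: ViewSpec, y, u, effect_mult: float) -> np.ndarray:
    """Gaussian-on-log-scale block: base feature means + latent + noise +
    class shift on the informative features."""
    n, p = len(y), view.n_features
    base = rng.normal(0.0, 1.0, size=p)
    x = base[None, :] + _LATENT_LOADING * u[:, None] + rng.normal(0.0, 1.0, size=(n, p))
    if view.n_informative:
        shift = view.effect_size * effect_mult
        x[:, : view.n_informative] += shift * y[:, None]
    return x


def _counts_block(rng, view: ViewSpec, y, u, effect_mult: float, depth: int) -> np.ndarray:
    """Dirichlet-multinomial counts; the informative components'
    log-concentrations differ between classes by the effect size."""
    n, p = len(y), view.n_features
    base_logalpha = rng.normal(0.0, 1.0, size=p)
    counts = np.zeros((n, p), dtype=int)
    shift = view.effect_size * effect_mult
    for i in range(n):
        logalpha = base_logalpha + _LATENT_LOADING_COUNTS * u[i]
        if view.n_informative:
            logalpha = logalpha.copy()
            logalpha[: view.n_informative] += shift * y[i]
        prob = rng.dirichlet(np.exp(logalpha))
        if view.zero_frac > 0:
            n_zero = int(np.floor(view.zero_frac * p))
            if n_zero:
                zero_idx = rng.choice(p, size=n_zero, replace=False)
                prob[zero_idx] = 0.0
                total = prob.sum()
                if total <= 0:
                    raise ValueError("zero_frac removed all mass from a sample")
                prob = prob / total
        counts[i] = rng.multinomial(depth, prob)
    return counts


def generate_cohort(spec: CohortSpec) -> tuple[dict, CohortMeta]:
    """Generate one :class:`FeatureTable` per (view, visit) pair plus metadata.

    Returns ``(tables, meta)`` where ``tables`` maps ``(view_name, visit)``
    to a FeatureTable whose rows are subject ids.  Fully deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = [f"S{i:03d}" for i in range(spec.n_subjects)]

    outcome = np.zeros(spec.n_subjects, dtype=int)
    pos_idx = rng.choice(spec.n_subjects, size=spec.n_positive, replace=False)
    outcome[pos_idx] = 1
    outcomes = pd.Series(outcome, index=subjects)
    meta = CohortMeta.from_subjects(outcomes, spec.visits)

    # per-subject latent effect with cross-visit correlation subject_corr
    z = rng.normal(0.0, 1.0, size=spec.n_subjects)
    rho = spec.subject_corr
    latents = {}
    for visit in spec.visits:
        eps = rng.normal(0.0, 1.0, size=spec.n_subjects)
        latents[visit] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps

    tables: dict = {}
    for view in spec.view_specs:
        for visit, mult in zip(spec.visits, spec.visit_effect_multipliers):
            u = latents[visit]
            if view.modality == "counts":
                x = _counts_block(rng, view, outcome, u, mult, spec.depth)
                df = pd.DataFrame(x, index=subjects, columns=view.feature_ids())
            elif view.modality == "intensity":
                g = _continuous_block(rng, view, outcome, u, mult)
                raw = np.power(2.0, g + 10.0)
                if view.zero_frac > 0:
                    raw[rng.random(raw.shape) < view.zero_frac] = 0.0
                df = pd.DataFrame(raw, index=subjects, columns=view.feature_ids())
            elif view.modality == "metabolite":
                g = _continuous_block(rng, view, outcome, u, mult)
                df = pd.DataFrame(g, index=subjects, columns=view.feature_ids())
                if view.censor_frac > 0:
                    cutoffs = df.quantile(view.censor_frac, axis=0)
                    df = df.mask(df.lt(cutoffs, axis=1))
            elif view.modality == "clinical":
                g = _continuous_block(rng, view, outcome, u, mult)
                df = pd.DataFrame(g, index=subjects, columns=view.feature_ids())
                # integer-code the second half of the columns (categorical-ish)
                half = view.n_features // 2
                if half:
                    cat = df.iloc[:, view.n_features - half :]
                    df.iloc[:, view.n_features - half :] = (
                        np.rint(cat.clip(-3, 3)) + 3
                    ).astype(float)
            else:  # npx: already log-scale Gaussian
                g = _continuous_block(rng, view, outcome, u, mult)
                df = pd.DataFrame(g, index=subjects, columns=view.feature_ids())
            tables[(view.name, visit)] = FeatureTable(
                values=df, modality=view.modality, name=view.name
            )

    for view_name, visit, subject in spec.missing_cells:
        key = (view_name, visit)
        if key not in tables:
            raise KeyError(f"missing_cells names unknown table {key}")
        ft = tables[key]
        tables[key] = ft.with_values(ft.values.drop(index=subject))
    return tables, meta


# ---------------------------------------------------------------------------
# I/O helpers (CLI `simulate` output layout)
# ---------------------------------------------------------------------------

def write_cohort(tables: dict, meta: CohortMeta, spec: CohortSpec, out_dir: str | Path) -> None:
    """Write one CSV per (view, visit), ``meta.csv`` and ``manifest.yaml``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"visits": list(spec.visits), "views": []}
    for view in spec.view_specs:
        entry = {"name": view.name, "modality": view.modality, "files": {}}
        for visit in spec.visits:
            fname = f"{view.name}__{visit}.csv"
            tables[(view.name, visit)].to_csv(out / fname)
            entry["files"][visit] = fname
        manifest["views"].append(entry)
    meta.to_csv(out / "meta.csv")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def load_cohort(in_dir: str | Path) -> tuple[dict, CohortMeta]:
    """Load a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text())
    tables = {}
    for entry in manifest["views"]:
        for visit, fname in entry["files"].items():
            tables[(entry["name"], visit)] = FeatureTable.from_csv(
                src / fname, modality=entry["modality"], name=entry["name"]
            )
    meta = CohortMeta.from_csv(src / "meta.csv")
    return tables, meta
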