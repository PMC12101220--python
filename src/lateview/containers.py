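"""Core data containers shared by every pipeline stage.

A :class:`FeatureTable` is one view's samples × features matrix.  Missing
values are encoded as NaN in the underlying :class:`pandas.DataFrame`;
``missing_mask`` exposes them explicitly.  :class:`CohortMeta` holds the
per-sample bookkeeping (subject id, visit label, binary outcome) that the
grouped splitting logic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "CohortMeta"]

#: modalities the synthetic generator and default recipes know about
KNOWN_MODALITIES = ("counts", "intensity", "npx", "metabolite", "clinical")


@dataclass
class FeatureTable:
    """One view's numeric matrix (samples as rows, features as columns).

    Parameters
    ----------
    values
        Numeric matrix with unique sample ids as the index and unique
        feature ids as the columns.  NaN entries are treated as missing.
    modality
        Free-form tag describing the data type (e.g. ``"counts"``).
    name
        Optional view name, used for feature prefixes when concatenating.
    """

    values: pd.DataFrame
    modality: str
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids in feature table")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids in feature table")
        non_numeric = [
            c for c, dt in self.values.dtypes.items() if not np.issubdtype(dt, np.number)
        ]
        if non_numeric:
            raise TypeError(f"non-numeric feature columns: {non_numeric[:5]}")

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean matrix; True where the value is missing."""
        return self.values.isna()

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "FeatureTable":
        return replace(self, values=self.values.copy())

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        return replace(self, values=values)

    def select_features(self, features: Sequence) -> "FeatureTable":
        return self.with_values(self.values.loc[:, list(features)])

    def select_samples(self, samples: Sequence) -> "FeatureTable":
        return self.with_values(self.values.loc[list(samples)])

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path, modality: str, name: str = "") -> "FeatureTable":
        values = pd.read_csv(path, index_col="sample_id")
        values.index.name = None
        return cls(values=values, modality=modality, name=name)


@dataclass
class CohortMeta:
    """Per-sample metadata: subject id, visit and binary outcome.

    One row per (subject, visit).  Outcome is constant within a subject;
    positive (1) is the persistent/minority class.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "visit", "outcome")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"meta table lacks columns: {missing}")
        bad = set(self.frame["outcome"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"outcome must be binary 0/1, got {sorted(bad)}")
        per_subject = self.frame.groupby("subject_id", sort=False)["outcome"].nunique()
        if (per_subject > 1).any():
            offenders = per_subject[per_subject > 1].index.tolist()
            raise ValueError(f"outcome varies within subject(s): {offenders}")

    # -- views ---------------------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.frame["subject_id"]))

    @property
    def visits(self) -> list:
        return list(dict.fromkeys(self.frame["visit"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_outcomes(self) -> pd.Series:
        """Outcome per subject, in first-appearance order."""
        s = self.frame.drop_duplicates("subject_id").set_index("subject_id")["outcome"]
        return s.astype(int)

    def subjects_with_outcome(self, outcome: int) -> list:
        s = self.subject_outcomes
        return list(s.index[s == outcome])

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortMeta":
        return cls(frame=pd.read_csv(path))

    @classmethod
    def from_subjects(
        cls, outcomes: pd.Series | dict, visits: Iterable
    ) -> "CohortMeta":
        """Build a (subject × visit) metadata table from per-subject outcomes."""
        outcomes = pd.Series(outcomes)
        rows = [
            {"subject_id": s, "visit": v, "outcome": int(o)}
            for s, o in outcomes.items()
            for v in visits
        ]
        return cls(frame=pd.DataFrame(rows))
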