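"""Labelled subject cohorts.

A :class:`CohortDataset` wraps a pandas DataFrame with one row per subject
and carries the binary neuropathy label, a provenance flag (original
measurement vs synthetic KDE draw), per-exercise feature columns named
``<exercise>__<feature>``, optional electrodiagnostic columns named
``edx__<parameter>`` and optional demographics (``age``, ``sex``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_extraction import EXERCISES

NEGATIVE_LABEL = "no_DN"
POSITIVE_LABEL = "DN"
LABELS = (NEGATIVE_LABEL, POSITIVE_LABEL)

EDX_PREFIX = "edx__"
META_COLUMNS = ("subject_id", "label", "provenance", "age", "sex")


def feature_column(exercise: str, feature: str) -> str:
    if exercise not in EXERCISES:
        raise ValueError(f"unknown exercise {exercise!r}")
    return f"{exercise}__{feature}"


def split_feature_column(column: str) -> tuple[str, str]:
    exercise, _, feature = column.partition("__")
    return exercise, feature


@dataclass
class CohortDataset:
    """One row per subject: label, provenance, features, optional EDx/demographics."""

    frame: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        frame = self.frame.reset_index(drop=True)
        if "subject_id" not in frame.columns or "label" not in frame.columns:
            raise ValueError("cohort frame requires 'subject_id' and 'label' columns")
        bad = set(frame["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"labels must be in {LABELS}; found {sorted(bad)}")
        if "provenance" not in frame.columns:
            frame = frame.assign(provenance="original")
        bad_prov = set(frame["provenance"]) - {"original", "synthetic"}
        if bad_prov:
            raise ValueError(f"provenance must be original|synthetic; found {sorted(bad_prov)}")
        if frame["subject_id"].duplicated().any():
            raise ValueError("subject_id values must be unique")
        self.frame = frame

    # -- column groups -------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if c not in META_COLUMNS and not c.startswith(EDX_PREFIX)
        ]

    @property
    def edx_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(EDX_PREFIX)]

    def exercise_columns(self, exercise: str) -> list[str]:
        prefix = f"{exercise}__"
        return [c for c in self.feature_columns if c.startswith(prefix)]

    # -- views ---------------------------------------------------------
    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def y(self) -> np.ndarray:
        """Binary outcome, 1 = diabetic neuropathy."""
        return (self.frame["label"] == POSITIVE_LABEL).to_numpy(dtype=int)

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def __len__(self) -> int:
        return len(self.frame)

    def class_counts(self) -> dict[str, int]:
        counts = self.frame["label"].value_counts()
        return {label: int(counts.get(label, 0)) for label in LABELS}

    def subset(self, mask) -> "CohortDataset":
        return CohortDataset(self.frame.loc[mask].reset_index(drop=True), seed=self.seed)
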