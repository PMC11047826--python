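"""File formats and run configuration.

* Signal CSV: one file per sensor per exercise, header
  ``t,ax,ay,az,gx,gy,gz``; missing (streaming-lost) samples are empty
  fields; a YAML sidecar carries sample rate, placement, exercise, eye
  condition and subject id.
* Feature tables: canonical long form
  ``subject_id,group,provenance,exercise,feature_name,value`` plus a wide
  view (one row per subject, ``<exercise>__<feature>`` columns). Both
  round-trip losslessly for finite values.
* EDx table CSV: ``subject_id,nerve,side,fiber,site,latency_ms,amplitude,cv_mps``.
* :class:`RunConfig`: every pipeline constant in one validated, YAML-
  serializable record so a run is reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, split_feature_column
from .signal_processing import ImuSeries

SIGNAL_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


def write_signal_csv(series: ImuSeries, path, sidecar: dict | None = None) -> None:
    path = Path(path)
    frame = pd.DataFrame({c: getattr(series, c) for c in SIGNAL_COLUMNS})
    frame.loc[series.gap_mask, list(SIGNAL_COLUMNS[1:])] = np.nan
    frame.to_csv(path, index=False, na_rep="")
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("sample_rate", series.sample_rate)
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def read_signal_csv(path, sample_rate: float | None = None) -> ImuSeries:
    path = Path(path)
    if sample_rate is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"{path}: no sample_rate given and sidecar {sidecar.name} not found"
            )
        with open(sidecar) as fh:
            sample_rate = float(yaml.safe_load(fh)["sample_rate"])
    frame = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    gap_mask = frame[list(SIGNAL_COLUMNS[1:])].isna().any(axis=1).to_numpy()
    return ImuSeries(
        sample_rate,
        frame["t"].to_numpy(dtype=float),
        gap_mask=gap_mask,
        **{c: frame[c].to_numpy(dtype=float) for c in SIGNAL_COLUMNS[1:]},
    )


def read_sidecar(path) -> dict:
    with open(Path(path).with_suffix(".yaml")) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def cohort_to_long(cohort: CohortDataset) -> pd.DataFrame:
    rows = []
    for _, row in cohort.frame.iterrows():
        for col in cohort.feature_columns:
            exercise, feature = split_feature_column(col)
            rows.append(
                {
                    "subject_id": row["subject_id"],
                    "group": row["label"],
                    "provenance": row["provenance"],
                    "exercise": exercise,
                    "feature_name": feature,
                    "value": row[col],
                }
            )
    return pd.DataFrame(rows)


def long_to_cohort(long: pd.DataFrame) -> CohortDataset:
    required = {"subject_id", "group", "exercise", "feature_name", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"long feature table missing column(s) {sorted(missing)}")
    long = long.copy()
    if "provenance" not in long.columns:
        long["provenance"] = "original"
    long["column"] = long["exercise"] + "__" + long["feature_name"]
    wide = long.pivot_table(
        index=["subject_id", "group", "provenance"], columns="column", values="value",
        sort=False,
    ).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"group": "label"})
    return CohortDataset(wide)


def write_feature_csv(cohort: CohortDataset, path, form: str = "long") -> None:
    if form == "long":
        cohort_to_long(cohort).to_csv(path, index=False)
    elif form == "wide":
        cohort.frame.to_csv(path, index=False)
    else:
        raise ValueError("form must be 'long' or 'wide'")


def read_feature_csv(path, form: str = "long") -> CohortDataset:
    frame = pd.read_csv(path)
    if form == "long":
        return long_to_cohort(frame)
    if form == "wide":
        return CohortDataset(frame)
    raise ValueError("form must be 'long' or 'wide'")


EDX_CSV_COLUMNS = (
    "subject_id", "nerve", "side", "fiber", "site", "latency_ms", "amplitude", "cv_mps",
)


def read_edx_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in EDX_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: EDx table missing column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# run configuration and manifests
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Every numeric constant of the pipeline, validated and serializable."""

    sample_rate: float = 100.0
    cutoff_hz: float = 0.1
    filter_order: int = 4
    window_length: int = 256
    overlap_fraction: float = 0.5
    band_cutoffs_hz: tuple[float, ...] = (5.0, 10.0, 15.0)
    contrast_mode: str = "ratio"
    max_gap_samples: int = 10
    n_negative: int = 200
    n_positive: int = 200
    train_fraction: float = 0.7
    model_kind: str = "svm"
    p_threshold: float = 0.05
    corr_threshold: float = 0.9
    decision_threshold: float = 0.5
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.cutoff_hz:
            raise ValueError("sample_rate must exceed twice the filter cutoff")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_negative < 0 or self.n_positive < 0:
            raise ValueError("augmentation counts must be nonnegative")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        self.band_cutoffs_hz = tuple(float(f) for f in self.band_cutoffs_hz)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["band_cutoffs_hz"] = list(self.band_cutoffs_hz)
        return data


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """Record config + seed + package version so a run can be replayed."""
    from . import __version__

    manifest = {"config": config.to_dict(), "version": __version__}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
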