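"""Spectral and eye-condition contrast features from preprocessed signals.

The feature family is built on Welch power-spectral-density estimates of
the gravity-free acceleration norm. Each band feature ``psd_<fx>hz`` is the
cumulative sum of PSD bins from the first bin at or above ``fx`` through
the end of the spectrum — total power at or above the cutoff. Default
cutoffs are 5, 10 and 15 Hz. For exercises performed both with eyes open
and eyes closed, contrast features (open/closed ratio or difference)
capture the loss of proprioceptive compensation that visual feedback
normally masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_processing import (
    ImuSeries,
    ScalarSignal,
    SignalError,
    compute_norm,
    fill_gaps,
    remove_gravity,
)

#: The six instrumented neurological maneuvers.
EXERCISES = (
    "heel_toe_walk",
    "tandem_walk",
    "romberg",
    "postural_tremor",
    "finger_nose",
    "heel_knee",
)

#: Exercises instrumented on the feet vs the backs of the hands.
LEG_EXERCISES = ("heel_toe_walk", "tandem_walk", "heel_knee")
ARM_EXERCISES = ("romberg", "postural_tremor", "finger_nose")

HAND_PLACEMENTS = ("left_hand", "right_hand")
FOOT_PLACEMENTS = ("left_foot", "right_foot")
PLACEMENTS = HAND_PLACEMENTS + FOOT_PLACEMENTS


def required_placements(exercise: str) -> tuple[str, ...]:
    return FOOT_PLACEMENTS if exercise in LEG_EXERCISES else HAND_PLACEMENTS


@dataclass
class PsdEstimate:
    """Welch PSD: frequencies (Hz, from 0 to Nyquist) and power per bin."""

    freqs: np.ndarray
    power: np.ndarray
    window_length: int
    overlap_fraction: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != self.power.size:
            raise ValueError("freqs and power must have equal length")
        if self.freqs[0] != 0:
            raise ValueError("PSD frequency grid must start at 0")
        if np.any(self.power < 0):
            raise ValueError("PSD power must be nonnegative")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class ExerciseRecording:
    """One exercise attempt: per-placement six-axis series plus metadata."""

    exercise: str
    sensors: dict  # placement -> ImuSeries
    eye_condition: str = "not_applicable"  # open | closed | not_applicable
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}; expected one of {EXERCISES}")
        if self.eye_condition not in ("open", "closed", "not_applicable"):
            raise ValueError(f"invalid eye_condition {self.eye_condition!r}")
        if not self.sensors:
            raise ValueError("recording has no sensors")
        for placement, series in self.sensors.items():
            if placement not in PLACEMENTS:
                raise ValueError(f"unknown placement {placement!r}")
            if not isinstance(series, ImuSeries):
                raise TypeError(f"sensor {placement!r} is not an ImuSeries")
        missing = [p for p in required_placements(self.exercise) if p not in self.sensors]
        if missing:
            raise ValueError(
                f"exercise {self.exercise!r} requires sensor placement(s) {missing}"
            )
        durations = {p: len(s) / s.sample_rate for p, s in self.sensors.items()}
        for placement, dur in durations.items():
            if not (5.0 <= dur <= 60.0):
                raise ValueError(
                    f"sensor {placement!r} duration {dur:.1f}s outside the 5-60 s exercise range"
                )

    @property
    def duration(self) -> float:
        series = next(iter(self.sensors.values()))
        return len(series) / series.sample_rate


@dataclass
class FeatureVector:
    """Named scalar features for one subject and one exercise."""

    subject_id: str
    exercise: str
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.features.items():
            if not np.isfinite(value):
                raise ValueError(f"feature {name!r} is not finite: {value}")


@dataclass
class FeatureConfig:
    """Knobs of the feature pipeline.

    band_cutoffs_hz : cumulative-band cutoffs (Hz) for ``psd_<fx>hz`` features.
    contrast_mode   : "ratio" or "difference" for eyes-open vs eyes-closed.
    aggregate       : "mean" collapses left/right sensors to one value per
                      feature; "per_sensor" keeps a feature per placement.
    max_gap_samples : longest interior streaming gap the interpolator fills.
    cutoff_hz/filter_order : gravity-removal high-pass settings.
    """

    band_cutoffs_hz: tuple[float, ...] = (5.0, 10.0, 15.0)
    contrast_mode: str = "ratio"
    contrast_epsilon: float = 1e-12
    aggregate: str = "mean"
    max_gap_samples: int = 10
    cutoff_hz: float = 0.1
    filter_order: int = 4
    window_length: int = 256
    overlap_fraction: float = 0.5


def welch_psd(
    signal: ScalarSignal, window_length: int = 256, overlap_fraction: float = 0.5
) -> PsdEstimate:
    """Welch PSD: averaged Hann-windowed modified periodograms.

    Segments of ``window_length`` samples overlap by ``overlap_fraction``;
    each segment is mean-detrended before windowing.
    """
    if np.any(signal.gap_mask):
        raise SignalError("welch_psd requires a gap-free signal")
    if len(signal) < window_length:
        raise SignalError(
            f"signal of {len(signal)} samples is shorter than one Welch window "
            f"({window_length}); record a longer signal"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, power = sps.welch(
        signal.values,
        fs=signal.sample_rate,
        window="hann",
        nperseg=window_length,
        noverlap=int(round(window_length * overlap_fraction)),
        detrend="constant",
    )
    return PsdEstimate(freqs, power, window_length, overlap_fraction)


def band_power_above(psd: PsdEstimate, fx: float) -> float:
    """Cumulative band power: sum of PSD bins from the first bin ≥ ``fx`` up.

    ``fx = 0`` gives the total spectral sum. ``fx`` above the Nyquist
    selects no bins and returns 0 with a warning.
    """
    if fx < 0:
        raise ValueError(f"cutoff frequency must be nonnegative, got {fx}")
    if fx > psd.nyquist:
        warnings.warn(
            f"cutoff {fx} Hz above Nyquist {psd.nyquist} Hz: no bins qualify",
            stacklevel=2,
        )
        return 0.0
    return float(np.sum(psd.power[psd.freqs >= fx]))


def contrast_feature(
    value_open: float,
    value_closed: float,
    mode: str = "ratio",
    epsilon: float | None = None,
) -> float:
    """Eyes-open vs eyes-closed contrast: ratio ``open/closed`` or difference."""
    if not (np.isfinite(value_open) and np.isfinite(value_closed)):
        raise ValueError("contrast inputs must be finite")
    if mode == "difference":
        return float(value_open - value_closed)
    if mode == "ratio":
        if value_closed == 0:
            if epsilon is None:
                raise ZeroDivisionError(
                    "eyes-closed value is zero; configure an epsilon guard for ratio mode"
                )
            value_closed = epsilon
        return float(value_open / value_closed)
    raise ValueError(f"mode must be 'ratio' or 'difference', got {mode!r}")


def _preprocess(series: ImuSeries, config: FeatureConfig) -> ScalarSignal:
    norm = compute_norm(series, source="accel")
    norm = fill_gaps(norm, max_gap_samples=config.max_gap_samples)
    return remove_gravity(norm, cutoff_hz=config.cutoff_hz, order=config.filter_order)


def _band_features(series: ImuSeries, config: FeatureConfig) -> dict[str, float]:
    clean = _preprocess(series, config)
    psd = welch_psd(clean, config.window_length, config.overlap_fraction)
    return {
        _band_name(fx): band_power_above(psd, fx) for fx in config.band_cutoffs_hz
    }


def _band_name(fx: float) -> str:
    return f"psd_{fx:g}hz"


def extract_features(
    recording: ExerciseRecording, config: FeatureConfig | None = None
) -> FeatureVector:
    """Full chain norm → gap fill → gravity removal → Welch PSD → band sums.

    With ``aggregate="mean"`` each band feature is the left/right sensor
    mean; with ``"per_sensor"`` features are prefixed by placement.
    Deterministic for a fixed recording.
    """
    config = config or FeatureConfig()
    placements = required_placements(recording.exercise)
    per_sensor = {p: _band_features(recording.sensors[p], config) for p in placements}
    features: dict[str, float] = {}
    if config.aggregate == "mean":
        for name in next(iter(per_sensor.values())):
            features[name] = float(np.mean([per_sensor[p][name] for p in placements]))
    elif config.aggregate == "per_sensor":
        for placement, bands in per_sensor.items():
            for name, value in bands.items():
                features[f"{placement}_{name}"] = value
    else:
        raise ValueError(f"unknown aggregate mode {config.aggregate!r}")
    return FeatureVector(recording.subject_id or "", recording.exercise, features)


def extract_contrast_features(
    recording_open: ExerciseRecording,
    recording_closed: ExerciseRecording,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Band features of each eye condition plus their open/closed contrasts."""
    config = config or FeatureConfig()
    if recording_open.exercise != recording_closed.exercise:
        raise ValueError("eye-condition pair must come from the same exercise")
    if (recording_open.eye_condition, recording_closed.eye_condition) != ("open", "closed"):
        raise ValueError("expected one eyes-open and one eyes-closed recording, in that order")
    fv_open = extract_features(recording_open, config)
    fv_closed = extract_features(recording_closed, config)
    features = {f"open_{k}": v for k, v in fv_open.features.items()}
    features.update({f"closed_{k}": v for k, v in fv_closed.features.items()})
    for name in fv_open.features:
        features[f"contrast_{name}"] = contrast_feature(
            fv_open.features[name],
            fv_closed.features[name],
            mode=config.contrast_mode,
            epsilon=config.contrast_epsilon,
        )
    return FeatureVector(fv_open.subject_id, recording_open.exercise, features)
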