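"""Synthetic study data: exercise recordings and feature-level cohorts.

The study's patient recordings are not publicly available, so this module
generates statistically controlled stand-ins at two levels:

* **Signal level** — :func:`simulate_recording` emits six-axis inertial
  recordings of the six neurological exercises as gravity (1 g) plus a
  low-frequency postural sway oscillation, a tremor-band oscillation,
  optional step impulses for the walking tasks, and white noise. The
  ``severity`` dial (0 = healthy, 1 = pronounced neuropathy) scales
  tremor power up and step strength down, reflecting how neuropathy
  amplifies postural tremor and weakens foot strike.

* **Feature level** — :func:`simulate_feature_cohort` draws per-group
  Gaussian feature vectors whose means and SDs default to the published
  group summaries of the significant screening features (two per
  exercise), plus electrodiagnostic (nerve conduction) parameters coupled
  to the features through a latent-Gaussian regression construction with
  configurable target correlations. Ages and sex fractions default to the
  study's demographics. EDx group means/SDs are *synthetic* (clinically
  plausible values; the source tables print only correlations).

All generators are pure functions of their spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import NEGATIVE_LABEL, POSITIVE_LABEL, CohortDataset, feature_column
from .feature_extraction import (
    ARM_EXERCISES,
    EXERCISES,
    LEG_EXERCISES,
    ExerciseRecording,
    required_placements,
)
from .signal_processing import ImuSeries


# ---------------------------------------------------------------------------
# feature templates: published per-group mean ± SD of each screening feature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureTemplate:
    """Group-conditional Gaussian marginal of one feature."""

    exercise: str
    name: str
    mean_no_dn: float
    sd_no_dn: float
    mean_dn: float
    sd_dn: float
    lower_bound: float | None = None  # physical bound enforced by rejection

    @property
    def column(self) -> str:
        return feature_column(self.exercise, self.name)


def _ft(ex, name, m0, s0, m1, s1, lb=None):
    return FeatureTemplate(ex, name, m0, s0, m1, s1, lb)


#: All 24 screening features: (no-neuropathy mean ± SD, neuropathy mean ± SD).
#: Power-like features carry a nonnegativity bound.
FEATURE_TEMPLATES: tuple[FeatureTemplate, ...] = (
    _ft("heel_toe_walk", "feature_1", 0.011, 0.005, 0.005, 0.003, 0.0),
    _ft("heel_toe_walk", "feature_2", 1.481, 0.369, 1.402, 0.334),
    _ft("heel_toe_walk", "feature_3", 1.459, 0.300, 1.418, 0.363),
    _ft("heel_toe_walk", "feature_4", 0.107, 0.048, 0.056, 0.031, 0.0),
    _ft("tandem_walk", "feature_5", 1.481, 0.206, 1.327, 0.135),
    _ft("tandem_walk", "feature_6", 1.307, 0.094, 1.230, 0.138),
    _ft("heel_knee", "feature_7", 0.036, 0.029, 0.012, 0.009, 0.0),
    _ft("heel_knee", "feature_8", 0.068, 0.104, 0.021, 0.014, 0.0),
    _ft("heel_knee", "feature_9", 0.052, 0.072, 0.034, 0.059, 0.0),
    _ft("heel_knee", "feature_10", 0.695, 0.304, 0.442, 0.173, 0.0),
    _ft("romberg", "feature_11", 0.164, 0.131, 0.339, 0.265, 0.0),
    _ft("romberg", "feature_12", 0.109, 0.156, 0.298, 0.282, 0.0),
    _ft("romberg", "feature_13", 0.628, 0.140, 0.542, 0.169),
    _ft("romberg", "feature_14", 0.604, 0.173, 0.505, 0.190),
    _ft("postural_tremor", "feature_15", 0.017, 0.011, 0.011, 0.012, 0.0),
    _ft("postural_tremor", "feature_16", 0.020, 0.013, 0.013, 0.008, 0.0),
    _ft("postural_tremor", "feature_17", 1.044, 0.487, 0.707, 0.244),
    _ft("postural_tremor", "feature_18", 1.281, 0.788, 0.839, 0.370),
    _ft("postural_tremor", "feature_19", 0.638, 0.154, 0.569, 0.159),
    _ft("postural_tremor", "feature_20", 0.597, 0.172, 0.564, 0.164),
    _ft("finger_nose", "feature_21", 1.006, 0.025, 0.960, 0.062),
    _ft("finger_nose", "feature_22", 0.003, 0.012, -0.021, 0.033),
    _ft("finger_nose", "feature_23", 0.598, 0.195, 0.548, 0.156),
    _ft("finger_nose", "feature_24", 0.606, 0.202, 0.616, 0.218),
)

#: The twelve features with the strongest label association — two per
#: exercise — used as the default simulated screening panel.
IMPORTANT_FEATURES = (
    "feature_1", "feature_4",      # heel-toe walk
    "feature_5", "feature_6",      # tandem walk
    "feature_7", "feature_10",     # heel-knee
    "feature_11", "feature_12",    # Romberg
    "feature_16", "feature_17",    # postural tremor
    "feature_21", "feature_22",    # finger-nose
)


def default_feature_templates(names=IMPORTANT_FEATURES) -> tuple[FeatureTemplate, ...]:
    by_name = {t.name: t for t in FEATURE_TEMPLATES}
    return tuple(by_name[n] for n in names)


# ---------------------------------------------------------------------------
# EDx templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdxTemplate:
    """One nerve-conduction parameter: synthetic group marginals plus the
    target Pearson correlations with named features.

    The group means/SDs here are *synthetic placeholders* with clinically
    plausible magnitudes (the source reports only correlation structure);
    the sign/magnitude pattern of ``feature_correlations`` follows the
    published feature-vs-EDx correlation table.
    """

    name: str  # e.g. "cv_lm_pr": conduction velocity, left medianus, pr site
    units: str
    mean_no_dn: float
    sd_no_dn: float
    mean_dn: float
    sd_dn: float
    feature_correlations: tuple[tuple[str, float], ...] = ()

    @property
    def column(self) -> str:
        return f"edx__{self.name}"


DEFAULT_EDX_TEMPLATES: tuple[EdxTemplate, ...] = (
    EdxTemplate(
        "cv_lm_pr", "m/s", 55.0, 4.0, 46.0, 5.0,
        (("heel_toe_walk__feature_1", 0.65), ("heel_toe_walk__feature_4", 0.55)),
    ),
    EdxTemplate(
        "lat_lm_rp", "ms", 3.2, 0.4, 4.2, 0.6,
        (("heel_knee__feature_7", 0.72), ("postural_tremor__feature_16", -0.58)),
    ),
    EdxTemplate(
        "amp_rp_se", "mV", 6.0, 2.0, 2.5, 1.5,
        (("heel_knee__feature_7", -0.60), ("finger_nose__feature_21", 0.50)),
    ),
    EdxTemplate(
        "cv_lp_ps", "m/s", 47.0, 4.0, 38.0, 5.0,
        (("heel_knee__feature_7", -0.65), ("heel_knee__feature_10", -0.28)),
    ),
)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSimSpec:
    """Conditions of a simulated feature-level cohort.

    Defaults mirror the pilot study: 15 non-neuropathy vs 8 neuropathy
    subjects, the twelve most discriminative features, ages
    50.7 ± 12.0 vs 63.8 ± 8.5 years, male fractions 5/15 and 3/8.
    """

    n_no_dn: int = 15
    n_dn: int = 8
    feature_templates: tuple[FeatureTemplate, ...] = field(
        default_factory=default_feature_templates
    )
    edx_templates: tuple[EdxTemplate, ...] = field(
        default_factory=lambda: DEFAULT_EDX_TEMPLATES
    )
    age_mean_no_dn: float = 50.7
    age_sd_no_dn: float = 12.0
    age_mean_dn: float = 63.8
    age_sd_dn: float = 8.5
    male_fraction_no_dn: float = 5 / 15
    male_fraction_dn: float = 3 / 8
    include_edx: bool = True
    include_demographics: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_no_dn < 2 or self.n_dn < 2:
            raise ValueError("each group needs at least 2 subjects")
        for t in self.feature_templates:
            if t.sd_no_dn <= 0 or t.sd_dn <= 0:
                raise ValueError(f"template {t.name!r} needs positive SDs")
        for e in self.edx_templates:
            for feat, rho in e.feature_correlations:
                if not -1 < rho < 1:
                    raise ValueError(f"target correlation {rho} for {e.name}/{feat} out of (-1,1)")


def _edx_loadings(edx_templates, feature_columns) -> np.ndarray:
    """Regression loadings of each EDx parameter on the feature z-scores.

    Features are drawn independent within group, so the loading equals the
    target correlation and the residual variance is 1 − Σρ². A parameter
    whose targets imply negative residual variance makes the latent
    covariance non-positive-definite.
    """
    loadings = np.zeros((len(edx_templates), len(feature_columns)))
    col_idx = {c: j for j, c in enumerate(feature_columns)}
    for i, tpl in enumerate(edx_templates):
        for feat, rho in tpl.feature_correlations:
            if feat not in col_idx:
                raise ValueError(
                    f"EDx template {tpl.name!r} targets unknown feature {feat!r}"
                )
            loadings[i, col_idx[feat]] = rho
        ss = float(np.sum(loadings[i] ** 2))
        if ss >= 1.0:
            raise ValueError(
                f"correlation targets for EDx block {tpl.name!r} are infeasible: "
                f"sum of squared targets {ss:.3f} >= 1 (latent covariance not positive definite)"
            )
    return loadings


def _draw_group(rng, n, templates, edx_templates, loadings, group: str):
    """Feature + EDx draws for one group via the shared latent normal."""
    d = len(templates)
    max_rounds = 1000
    z = rng.standard_normal((n, d))
    means = np.array([t.mean_no_dn if group == NEGATIVE_LABEL else t.mean_dn for t in templates])
    sds = np.array([t.sd_no_dn if group == NEGATIVE_LABEL else t.sd_dn for t in templates])
    bounds = np.array(
        [-np.inf if t.lower_bound is None else t.lower_bound for t in templates]
    )
    # rejection against physical bounds (slight per-feature variance shrink)
    for _ in range(max_rounds):
        bad = (means + sds * z) < bounds
        if not bad.any():
            break
        z[bad] = rng.standard_normal(int(bad.sum()))
    features = means + sds * z

    edx = None
    if edx_templates:
        k = len(edx_templates)
        resid_sd = np.sqrt(1.0 - np.sum(loadings**2, axis=1))
        eps = rng.standard_normal((n, k))
        z_edx = z @ loadings.T + eps * resid_sd
        e_means = np.array(
            [t.mean_no_dn if group == NEGATIVE_LABEL else t.mean_dn for t in edx_templates]
        )
        e_sds = np.array(
            [t.sd_no_dn if group == NEGATIVE_LABEL else t.sd_dn for t in edx_templates]
        )
        edx = e_means + e_sds * z_edx
    return features, edx


def simulate_feature_cohort(spec: CohortSimSpec) -> CohortDataset:
    """Draw a labelled feature cohort (optionally with EDx and demographics).

    Per group, features are independent Gaussians with the template
    means/SDs (rejection-truncated at physical bounds); EDx parameters are
    linear combinations of the feature z-scores plus independent noise,
    calibrated so the within-group feature↔EDx Pearson correlations hit
    the templates' targets.
    """
    rng = np.random.default_rng(spec.seed)
    templates = spec.feature_templates
    feat_cols = [t.column for t in templates]
    edx_templates = spec.edx_templates if spec.include_edx else ()
    loadings = _edx_loadings(edx_templates, feat_cols) if edx_templates else None

    blocks = []
    for group, n in ((NEGATIVE_LABEL, spec.n_no_dn), (POSITIVE_LABEL, spec.n_dn)):
        features, edx = _draw_group(rng, n, templates, edx_templates, loadings, group)
        frame = pd.DataFrame(features, columns=feat_cols)
        frame.insert(0, "subject_id", [f"sim_{group}_{i:03d}" for i in range(n)])
        frame.insert(1, "label", group)
        frame.insert(2, "provenance", "original")
        if spec.include_demographics:
            if group == NEGATIVE_LABEL:
                age_mu, age_sd, male_frac = (
                    spec.age_mean_no_dn, spec.age_sd_no_dn, spec.male_fraction_no_dn,
                )
            else:
                age_mu, age_sd, male_frac = (
                    spec.age_mean_dn, spec.age_sd_dn, spec.male_fraction_dn,
                )
            frame["age"] = age_mu + age_sd * rng.standard_normal(n)
            frame["sex"] = np.where(rng.random(n) < male_frac, "male", "female")
        if edx is not None:
            for j, tpl in enumerate(edx_templates):
                frame[tpl.column] = edx[:, j]
        blocks.append(frame)
    return CohortDataset(pd.concat(blocks, ignore_index=True), seed=spec.seed)


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------


@dataclass
class SignalSimSpec:
    """Conditions of one simulated exercise recording.

    ``severity`` in [0, 1] drives the group contrast: tremor amplitude
    scales with ``0.2 + 0.8·severity`` and, for the walking exercises,
    step-impulse amplitude with ``1 − 0.6·severity`` (weakened foot
    strike). Amplitudes are accelerations in g.
    """

    exercise: str = "postural_tremor"
    severity: float = 0.0
    sample_rate: float = 100.0
    duration: float = 12.0
    tremor_band: tuple[float, float] = (4.0, 12.0)
    sway_band: tuple[float, float] = (0.3, 2.0)
    tremor_amplitude: float = 0.03
    sway_amplitude: float = 0.05
    noise_sd: float = 0.01
    gap_rate: float = 0.0
    eye_condition: str = "not_applicable"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")
        if not 5.0 <= self.duration <= 60.0:
            raise ValueError("duration must lie in [5, 60] s")
        nyq = self.sample_rate / 2
        for lo, hi in (self.tremor_band, self.sway_band):
            if not 0 < lo < hi < nyq:
                raise ValueError("oscillation bands must lie within (0, Nyquist)")
        if not 0.0 <= self.gap_rate < 0.2:
            raise ValueError("gap_rate must be a small probability in [0, 0.2)")


# direction of movement relative to the sensor; mostly vertical so the
# oscillation survives the norm's linearization around the 1 g offset
_MOVE_DIR = np.array([0.25, 0.25, 1.0]) / np.linalg.norm([0.25, 0.25, 1.0])


def _simulate_sensor(spec: SignalSimSpec, rng) -> ImuSeries:
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    tremor_gain = 0.2 + 0.8 * spec.severity
    sway_gain = 1.0
    if spec.eye_condition == "closed":
        # impaired proprioception shows once visual feedback is removed
        sway_gain *= 1.0 + spec.severity

    f_tremor = rng.uniform(*spec.tremor_band)
    f_sway = rng.uniform(*spec.sway_band)
    movement = spec.tremor_amplitude * tremor_gain * np.sin(
        2 * np.pi * f_tremor * t + rng.uniform(0, 2 * np.pi)
    )
    movement += spec.sway_amplitude * sway_gain * np.sin(
        2 * np.pi * f_sway * t + rng.uniform(0, 2 * np.pi)
    )
    if spec.exercise in ("heel_toe_walk", "tandem_walk"):
        step_amp = 0.15 * (1.0 - 0.6 * spec.severity)
        cadence = rng.uniform(1.2, 2.0)  # steps/s
        phase = 2 * np.pi * cadence * t
        movement += step_amp * np.clip(np.sin(phase), 0.0, None) ** 3

    accel = np.outer(movement, _MOVE_DIR)
    accel += spec.noise_sd * rng.standard_normal((n, 3))
    accel[:, 2] += 1.0  # gravity, g

    gyro = 20.0 * np.column_stack(
        [movement, 0.5 * movement, 0.2 * movement]
    ) + 0.5 * rng.standard_normal((n, 3))

    gap_mask = rng.random(n) < spec.gap_rate
    gap_mask[0] = gap_mask[-1] = False  # keep the grid anchored
    channels = {}
    for j, name in enumerate(("ax", "ay", "az")):
        col = accel[:, j].copy()
        col[gap_mask] = np.nan
        channels[name] = col
    for j, name in enumerate(("gx", "gy", "gz")):
        col = gyro[:, j].copy()
        col[gap_mask] = np.nan
        channels[name] = col
    return ImuSeries(spec.sample_rate, t, gap_mask=gap_mask, **channels)


def simulate_recording(spec: SignalSimSpec) -> ExerciseRecording:
    """Simulate one exercise attempt with the placements the exercise needs."""
    rng = np.random.default_rng(spec.seed)
    sensors = {p: _simulate_sensor(spec, rng) for p in required_placements(spec.exercise)}
    return ExerciseRecording(
        exercise=spec.exercise, sensors=sensors, eye_condition=spec.eye_condition
    )
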