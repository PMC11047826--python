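"""Signal- and feature-level synthetic generators."""

import numpy as np
import pytest

from neuroscreen import (
    CohortSimSpec,
    SignalSimSpec,
    compute_norm,
    extract_features,
    simulate_feature_cohort,
    simulate_recording,
)
from neuroscreen.synthetic_data import (
    DEFAULT_EDX_TEMPLATES,
    EdxTemplate,
    FeatureTemplate,
    default_feature_templates,
)


class TestSimulateFeatureCohort:
    def test_default_cohort_mirrors_pilot_study(self):
        cohort = simulate_feature_cohort(CohortSimSpec(seed=0))
        assert cohort.class_counts() == {"no_DN": 15, "DN": 8}
        assert len(cohort.feature_columns) == 12
        assert len(cohort.edx_columns) == 4
        assert {"age", "sex"} <= set(cohort.frame.columns)

    def test_group_means_recovered_at_large_n(self):
        tpl = default_feature_templates(("feature_1",))
        spec = CohortSimSpec(
            n_no_dn=10_000, n_dn=10_000, feature_templates=tpl,
            include_edx=False, include_demographics=False, seed=1,
        )
        cohort = simulate_feature_cohort(spec)
        col = "heel_toe_walk__feature_1"
        for label, mean, sd in (("no_DN", 0.011, 0.005), ("DN", 0.005, 0.003)):
            vals = cohort.frame.loc[cohort.frame.label == label, col]
            se = sd / np.sqrt(len(vals))
            # nonnegativity truncation shifts the mean slightly upward,
            # so allow the truncation bias on top of the sampling error
            assert abs(vals.mean() - mean) < 3 * se + 0.1 * sd

    def test_zero_target_correlations_give_independence(self):
        edx = (EdxTemplate("cv_test", "m/s", 50, 4, 40, 4, ()),)
        spec = CohortSimSpec(
            n_no_dn=5000, n_dn=5000, edx_templates=edx,
            include_demographics=False, seed=2,
        )
        cohort = simulate_feature_cohort(spec)
        for label in ("no_DN", "DN"):
            sub = cohort.frame[cohort.frame.label == label]
            for col in cohort.feature_columns[:4]:
                r = np.corrcoef(sub[col], sub["edx__cv_test"])[0, 1]
                assert abs(r) < 3 / np.sqrt(len(sub))

    def test_planted_negative_cv_correlation_recovered(self):
        """Latent-Gaussian construction hits the target correlation exactly
        for an unbounded feature; the nonnegativity rejection attenuates it
        for features whose mean sits close to zero."""
        rho = -0.65
        # same scale as the heel-knee feature but without the physical bound
        free = (FeatureTemplate("heel_knee", "feature_7", 0.036, 0.029, 0.012, 0.009),)
        edx = (
            EdxTemplate(
                "cv_lp_ps", "m/s", 47, 4, 38, 5,
                (("heel_knee__feature_7", rho),),
            ),
        )
        spec = CohortSimSpec(
            n_no_dn=2000, n_dn=2000, feature_templates=free, edx_templates=edx,
            include_demographics=False, seed=3,
        )
        cohort = simulate_feature_cohort(spec)
        sub = cohort.frame[cohort.frame.label == "no_DN"]
        r = np.corrcoef(sub["heel_knee__feature_7"], sub["edx__cv_lp_ps"])[0, 1]
        se = (1 - rho**2) / np.sqrt(len(sub))
        assert abs(r - rho) < 3 * se

        # with the default bounded template the sign and rough magnitude survive
        spec_bounded = CohortSimSpec(
            n_no_dn=2000, n_dn=2000, edx_templates=edx,
            include_demographics=False, seed=3,
        )
        sub_b = simulate_feature_cohort(spec_bounded).frame.query("label == 'no_DN'")
        r_b = np.corrcoef(sub_b["heel_knee__feature_7"], sub_b["edx__cv_lp_ps"])[0, 1]
        assert -0.75 < r_b < -0.5

    def test_infeasible_correlation_targets_name_the_block(self):
        edx = (
            EdxTemplate(
                "bad", "ms", 3, 1, 4, 1,
                (("heel_knee__feature_7", 0.9), ("heel_knee__feature_10", 0.9)),
            ),
        )
        with pytest.raises(ValueError, match="bad"):
            simulate_feature_cohort(CohortSimSpec(edx_templates=edx, seed=0))

    def test_pure_function_of_seed(self):
        a = simulate_feature_cohort(CohortSimSpec(seed=11)).frame
        b = simulate_feature_cohort(CohortSimSpec(seed=11)).frame
        assert a.equals(b)

    def test_nonnegative_bounds_respected(self):
        cohort = simulate_feature_cohort(CohortSimSpec(n_no_dn=2000, n_dn=2000, seed=4))
        for tpl in default_feature_templates():
            if tpl.lower_bound is not None:
                assert (cohort.frame[tpl.column] >= tpl.lower_bound).all()


class TestSimulateRecording:
    def test_gravity_only_recording_has_unit_norm(self):
        spec = SignalSimSpec(
            exercise="romberg", severity=0.0, tremor_amplitude=0.0,
            sway_amplitude=0.0, noise_sd=0.0, seed=0,
        )
        rec = simulate_recording(spec)
        for series in rec.sensors.values():
            assert np.allclose(compute_norm(series).values, 1.0, atol=1e-12)

    def test_required_placements_present(self):
        rec = simulate_recording(SignalSimSpec(exercise="heel_toe_walk", seed=1))
        assert set(rec.sensors) == {"left_foot", "right_foot"}
        rec = simulate_recording(SignalSimSpec(exercise="postural_tremor", seed=1))
        assert set(rec.sensors) == {"left_hand", "right_hand"}

    def test_fixed_seed_identical_recordings(self):
        spec = SignalSimSpec(exercise="finger_nose", severity=0.5, gap_rate=0.01, seed=9)
        a, b = simulate_recording(spec), simulate_recording(spec)
        for p in a.sensors:
            assert np.array_equal(a.sensors[p].ax, b.sensors[p].ax, equal_nan=True)
            assert np.array_equal(a.sensors[p].gap_mask, b.sensors[p].gap_mask)

    def test_gaps_marked_in_mask(self):
        spec = SignalSimSpec(exercise="romberg", gap_rate=0.02, seed=5)
        rec = simulate_recording(spec)
        series = rec.sensors["left_hand"]
        assert series.gap_mask.any()
        assert np.isnan(series.ax[series.gap_mask]).all()

    def test_severity_raises_tremor_band_power(self):
        """Planted severity gradient survives the real feature pipeline."""
        wins = 0
        n_pairs = 50
        for seed in range(n_pairs):
            feats = {}
            for sev in (0.0, 1.0):
                spec = SignalSimSpec(
                    exercise="postural_tremor", severity=sev, seed=seed,
                )
                feats[sev] = extract_features(simulate_recording(spec)).features["psd_5hz"]
            wins += feats[1.0] > feats[0.0]
        assert wins >= int(0.95 * n_pairs)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            SignalSimSpec(severity=1.5)
        with pytest.raises(ValueError, match="Nyquist"):
            SignalSimSpec(tremor_band=(4.0, 80.0))
        with pytest.raises(ValueError, match="duration"):
            SignalSimSpec(duration=2.0)
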