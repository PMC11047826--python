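# Methods

`neuroscreen` implements a desk-scale version of a wearable screening
pipeline for diabetic peripheral neuropathy (DN): four six-axis inertial
sensors (backs of both hands, tops of both feet) record six standardized
neurological exercises, spectral features are extracted per exercise, and
a per-exercise classifier ensemble outputs a DN probability.

## Signal model and preprocessing

Each sensor stream is a uniformly sampled six-axis series: tri-axial
acceleration in g and tri-axial angular velocity in deg/s. The sampling
rate is configurable and defaults to 100 Hz, a standard rate for
wearable inertial units; it is carried on every signal object rather
than assumed.

1. **Norm.** The per-sample Euclidean magnitude
   `norm = sqrt(x² + y² + z²)` of the acceleration triplet is the working
   signal. It is invariant under any fixed sensor rotation, which removes
   the dependence on how the strap was put on.
2. **Gap filling.** Samples lost in streaming are marked in a gap mask
   and reconstructed with a local degree-2 polynomial, least-squares
   fitted to the 3 nearest valid samples on each side of the gap (6
   support points). Gaps longer than `max_gap_samples` (default 10
   samples, i.e. 100 ms at 100 Hz) are an error rather than a guess;
   leading/trailing gaps are trimmed, never extrapolated. A quadratic
   through 6 points reproduces any quadratic trend exactly and keeps the
   fit overdetermined, so single-sample noise does not whip the
   interpolant around.
3. **Gravity removal.** A Butterworth high-pass with 0.1 Hz cut-off
   strips the quasi-static 1 g gravity component from the norm. The
   order (4) is a design choice; the filter is applied forward-backward
   (zero phase) so exercise events are not shifted in time, which matters
   for features that compare conditions. The two-pass magnitude response
   is the square of the single-pass response; tests check measured sine
   attenuation against the analytic order-4 Butterworth magnitude.

## Spectral features

The power spectral density of the gravity-free norm is estimated with
Welch's method: Hann-windowed, mean-detrended segments of 256 samples
with 50% overlap. Each band feature

    PSD_fx = Σ_{n = idx(fx)}^{N} PSD[n]

is the cumulative sum of PSD bins from the first bin at or above the
cutoff `fx` to the end of the spectrum — total power at or above `fx`.
Default cutoffs are 5, 10 and 15 Hz, which bracket the physiological
tremor band; the set is configurable. By construction
`PSD_5Hz ≥ PSD_10Hz ≥ PSD_15Hz` for every signal.

For exercises performed both with eyes open and closed, contrast
features compare the two conditions. The default mode is the ratio
`open/closed` with a 1e-12 epsilon guard (a difference mode is also
available): DN damages deep postural sensibility, so movement degrades
disproportionately once visual feedback is removed, pushing the ratio
away from 1. Left/right sensors are collapsed to their mean by default
(`aggregate="per_sensor"` keeps them separate).

## KDE augmentation

A pilot-scale cohort (tens of subjects) cannot support model training
directly. The training set is therefore expanded by class-conditional
kernel density estimation: per class, features are standardized to zero
mean/unit variance, a Gaussian product-kernel KDE is fitted with Scott's
rule bandwidth (`n^(-1/(d+4))` per standardized dimension; Silverman and
fixed bandwidths are options), and synthetic subjects are drawn as a
uniformly chosen training point plus per-dimension Gaussian noise. Draws
are mapped back to the original scale and flagged
`provenance="synthetic"`. Defaults add 200 negative and 200 positive
draws, so the 23-subject default cohort becomes a 423-row training set.
Originals always pass through bit-identical. Zero-variance features are
rejected rather than silently jittered.

The KDE is implemented in-package (the sampling contract and fixed
per-dimension bandwidths are part of the method); `scipy.stats.gaussian_kde`
serves as an independent cross-check in the test suite.

## Feature selection, per-exercise models, aggregation

Per exercise, features are selected by one-by-one backward elimination on
pooled two-sample t-test p-values (drop the largest p until all retained
p ≤ 0.05), followed by redundancy pruning: of any retained pair with
|Pearson r| > 0.9, the member with the smaller p survives. Ties are
broken by the larger mean absolute inter-feature correlation, then by
column order, so selection is deterministic.

One classifier is trained per exercise — SVM (default), logistic
regression or decision tree — inside a scaler + classifier pipeline,
with 5-fold cross-validated grid search. The SVM grid spans kernels
{linear, RBF, polynomial} × C ∈ {0.1, 1, 10}, because different
exercises separate linearly or not; the logistic grid spans C, the tree
grid depth. SVM margins are Platt-calibrated into probabilities
(`CalibratedClassifierCV`, single calibrated model rather than a CV
ensemble).

A subject's screening output is the arithmetic mean of the six
per-exercise positive-class probabilities,

    output_aggregated = (1/6) Σ_{i=1..6} ExerciseModel_i(X_i),

thresholded at 0.5 into the binary call. A missing exercise output is a
hard error by default; there is no silent renormalization.

The train/test split is stratified 70:30 by label, and jointly by
(label, provenance) when original and synthetic rows are mixed, so
measured subjects appear in the test side in proportion. Evaluation
reports per-class precision/recall/F1/support, sensitivity (DN recall),
specificity (non-DN recall), accuracy, and the ROC with trapezoidal AUC.

## Companion statistics

Group comparisons use the pooled-variance (Student) two-sample t-test,
from raw samples or from published summaries (mean, SD, n); the pooled
form reproduces the study's printed age comparison (p = 0.012 from
63.8 ± 8.5, n = 8 vs 50.7 ± 12.0, n = 15), which the Welch form does not
(p ≈ 0.007) — that agreement is why the pooled form is the default.
Contingency tables use the Pearson chi-square test (no continuity
correction); Mann-Whitney U with the asymptotic tie-corrected p-value is
the nonparametric fallback. Feature-vs-EDx association is a pairwise
Pearson matrix over pairwise-complete observations (≥ 3 pairs per cell);
cells with |r| < 0.100 are masked and serialize as empty CSV fields. The
binary DN indicator enters as a 0/1 column, making its correlations
point-biserial. No multiple-testing correction is applied by default
(raw p < 0.05 is the declared significance convention);
Benjamini–Hochberg adjustment is available.

## Synthetic data: what it emulates, what it does not

**Feature-level cohorts** draw per-group independent Gaussians for each
feature using the published group means ± SDs; the default panel is the
twelve most label-associated features, two per exercise. Power-like
features are truncated at zero by rejection, which shrinks their
variance slightly and biases their mean upward by a few percent of an SD
when the mean sits within ~1.5 SD of zero. Electrodiagnostic (nerve
conduction) parameters are generated as linear combinations of the
feature z-scores plus independent noise, calibrated so the within-group
feature↔EDx Pearson correlations hit configurable targets; targets whose
squared sum reaches 1 for one EDx parameter make the latent covariance
non-positive-definite and raise an error naming the block. The EDx group
means/SDs shipped as defaults are synthetic placeholders with clinically
plausible magnitudes (only the correlation structure is published);
their correlation targets follow the published sign/magnitude pattern
(e.g. conduction velocity negatively associated with DN, positively with
walk-dynamics features). Ages default to 50.7 ± 12.0 vs 63.8 ± 8.5
years and male fractions to 5/15 vs 3/8, matching the study's
demographics. Default group sizes are 15 vs 8.

Truncation caveat: planted correlations are exact on the untruncated
scale; for a bounded feature with mean ≈ 1.2 SD above zero the realized
|r| is attenuated by roughly 0.05–0.1.

**Signal-level recordings** are gravity (1 g along the vertical axis)
plus a sway oscillation (0.3–2 Hz), a tremor-band oscillation (4–12 Hz),
step impulses for the walking tasks, and white noise, with streaming
gaps injected at a configurable per-sample rate. Movement is oriented
mostly along the vertical so its spectrum survives the norm's
linearization around the 1 g offset. `severity` ∈ [0, 1] scales tremor
amplitude by `0.2 + 0.8·severity` and walk step amplitude by
`1 − 0.6·severity` (neuropathy expresses tremor and weakens foot
strike); eyes-closed recordings scale sway by `1 + severity`. These
recordings are spectrally plausible but not biomechanical gait models:
they contain no stride variability, no orientation drift, and no
subject-specific morphology. Tests passing on them demonstrate the
pipeline's signal-processing and statistical behaviour, not clinical
performance on real patients.

Within-subject correlation across exercises is unknown and defaults to
none (features independent given the group); the feature panel is drawn
per subject in one latent block, so a shared subject factor could be
added without changing the interfaces.

## Benchmark protocol and problem sizes

`neuroscreen.benchmark.screening_benchmark` characterizes the ensemble's
operating point end to end: simulate 100 subjects per group from the
published feature templates, augment with 200 + 200 KDE draws, select
features, grid-search per-exercise SVMs, split 70:30, aggregate, score
the held-out split; repeat over 20 independent seeds spawned from one
base seed. 100 subjects per group keeps Monte-Carlo noise on the mean
metrics below a percentage point while one replicate runs in seconds.
Because the twelve planted group differences compound across six
exercises, the synthetic task is easier than the clinical one: the
published operating point (sensitivity 0.78, specificity 0.87, accuracy
82.1%) is a floor the benchmark clears, not a quantity it reproduces.
The withheld real-data metrics table and the real correlation matrix are
not reproducible from synthetic data and are not claimed.

## Numerical and degenerate-input conventions

- Filters require signals longer than the filter warm-up
  (`3·(2·n_sections + 1)` samples); shorter input is an error.
- Welch requires at least one full window (256 samples); band cutoffs
  above the Nyquist yield 0 with a warning.
- Ratio contrasts guard a zero denominator with epsilon 1e-12 (error if
  the guard is disabled).
- A t-test with zero pooled variance returns p = 1 when the means agree
  and errors when they differ.
- All stochastic operations take explicit seeds; replicate seeds are
  spawned with `numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

- The proprietary definitions of the 24 production features are not
  public; the implemented family (PSD band sums plus open/closed
  contrasts) covers the disclosed members, and the feature-level
  generator works from the published group statistics of the obfuscated
  features directly.
- Gravity rejection uses the demonstrated high-pass route only;
  gyroscope-based orientation tracking is out of scope.
- The synthetic benchmark bounds pipeline correctness, not clinical
  accuracy (see above).
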