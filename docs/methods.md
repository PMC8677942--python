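# Methods

`phnrlab` analyses photopic full-field electroretinograms (ERGs) recorded
with a handheld skin-electrode device, with the photopic negative response
(PhNR) — the slow negative component after the b-wave that reflects
retinal ganglion cell activity — as the quantity of interest for detecting
optic neuropathy (ON). Because the underlying clinical waveforms are not
public, the package pairs every analysis stage with a synthetic cohort
generator that plants known ground truth, so the statistical and
classification machinery can be validated end to end.

## Data model

A recording is an averaged waveform of `n_samples` potentials in µV over
`duration_ms`, by default 430 samples over 220 ms with the flash at
100 ms. Sample *i* is assigned time `i·dt` with `dt = duration/n_samples`
(0-based). Under this convention 11 consecutive samples span
`11·220/430 = 5.63 ms`, matching the conventional ~5.62 ms trough-averaging
window; the alternative `dt = duration/(n−1)` differs only in the fourth
significant digit but is not used. `sample_at_time` rounds to the nearest
sample, ties toward the smaller index, and accepts `t = duration` as the
last sample.

Stimulus time is a per-record field (default 100 ms) rather than a global
constant so other protocols remain representable. Labels are
`ON_POS`/`ON_NEG`/`UNKNOWN`; eye classes subdivide ON (acute/chronic) and
controls (fellow/patient/healthy). Missing covariates are represented as
absent values, never numeric sentinels.

Two table dialects are provided: long-form CSV (one row per sample;
convenient for external tools) and JSON (samples as arrays). Floats are
written with `repr`, the shortest round-tripping decimal, so
read→write→read is byte-stable.

## Feature extraction

All features are computed on the detrended trace, in this order:

1. **Linear detrend** — subtract the OLS line fitted over the whole
   record (the standard `detrend` behaviour). A `detrend_scope =
   "prestimulus"` option fits the line on pre-stimulus samples only.
2. **Baseline** — mean of samples strictly before the stimulus.
3. **b-wave peak** — maximum within `[stim, stim+150 ms]` (configurable).
   An unrestricted argmax could land on pre-stimulus artifact, hence the
   window. Ties break to the earliest sample.
4. **a-wave trough** — minimum on `[stim, b-peak]`.
5. **PhNR_72** — the single sample nearest `stim+72 ms`, minus baseline
   (no interpolation or averaging).
6. **PhNR_min** — minimum within `stim+72±10 ms` (inclusive bounds), then
   the mean of the 11 samples centred on that minimum, minus baseline. If
   the 11-point span would leave the record it is clipped and flagged.
7. **Ratios** — `P = −PhNR/b_amp`, `W = (b_amp − PhNR)/(b_amp − a_amp)`,
   using the trough-averaged PhNR by default (configurable to PhNR_72).

Sign convention: amplitudes are `value − baseline`, signed, so a PhNR
below baseline is negative (−2.8 ± 1.5 µV in ON eyes, −3.7 ± 1.8 µV in
controls in the motivating clinical cohort) and the P-ratio numerator
`−PhNR` is positive for normal waveforms. `a_amp` is the signed a-trough
depth; `b_amp = b_peak − a_trough` is trough-to-peak and non-negative
whenever QC passes.

### Detrend scope and PhNR shrinkage

Full-record detrending of a waveform whose components sit mostly in the
post-stimulus half tilts the trace: the fitted line absorbs part of the
slow PhNR mass. On noiseless synthetic composites this shrinks the
extracted `PhNR_min` toward zero by roughly a third at clinical
amplitudes (e.g. −3.7 µV planted → ≈ −2.4 µV extracted) and shifts the
apparent trough ≈1.6 ms earlier, while `b_amp` (a differential over
~17 ms) moves by under 2%. Because the shrinkage is roughly proportional,
group *contrasts* and ROC orderings are preserved, which is why the
default remains the full-record fit used in practice on drifting
recordings. The pre-stimulus scope removes the artifact entirely on
drift-free data (bias < 0.01 µV) and is used by the generator-validation
tests that check extractor unbiasedness.

### Quality control

QC is automated (the original study reviewed waveforms manually):

- **No defined b-wave**: `b_amp ≤ 8 ×` pre-stimulus SD. The factor is 8,
  not a small multiple, because the expected peak-to-trough range of
  ~300 Gaussian noise samples is already ≈6.7 SD; pure-noise records
  therefore sit just below the threshold while realistic waveforms
  (b_amp ≈ 12 µV, noise ≤ 1 µV) sit far above it.
- **Amplitude bound**: any |sample| > 200 µV (electrode artifact).
- **Clipped trough window**: the 11-point average hit a record edge.
- **Manual override**: an explicit record-id exclusion list is honoured.

Undefined ratios (non-positive `b_amp`, or `b_amp = a_amp`) also fail QC;
the reasons list every violated rule.

Snellen acuities convert to logMAR as `log10(X/20)` (or `log10(X/6)`);
count fingers, hand motions and no light perception map to 2, 3 and 6.

## Group statistics (GEE)

Eyes and repeated recordings cluster within subjects, so group contrasts
use linear generalized estimating equations with subjects as clusters,
exchangeable working correlation by default (independence available) and
robust sandwich standard errors; p-values are two-sided normal-reference
Wald tests without small-sample correction. The solver is statsmodels'
GEE; this module owns the model contracts and returns coefficients,
robust SEs, z and p per term. Missing covariates are removed listwise per
model. Models provided: feature vs ON status (optionally age-adjusted —
age only, as no other adjustment set is defined), control-source
contrasts (fellow vs other controls; healthy vs other), and
structure–function regressions on HVF mean deviation or OCT thicknesses
(RNFL/GCL+IPL models exclude acute ON eyes, whose disc swelling inflates
thickness).

## Diagnostic evaluation

ROC analysis takes one eye per subject (right eye unless only the left
contributed) after averaging features across an eye's recordings.
Thresholds are midpoints between consecutive distinct scores plus the two
infinite endpoints, so the curve always contains (sens 1, spec 0) and
(sens 0, spec 1). Orientation (whether high or low scores indicate
disease) is chosen per feature so AUC ≥ 0.5 and is recorded in the
output; ON eyes have *less negative* PhNR, so for signed PhNR higher is
positive. AUC is the trapezoidal area; the Youden point maximizes
`J = sens + spec − 1`, ties resolving to the smallest finite cutoff.

Confusion metrics are reported in two modes. The standard mode uses
`precision = TP/(TP+FP)` and `F1 = 2PR/(P+R)`. The reproduction mode
applies, verbatim, the definitions used in the motivating study's
machine-learning comparison: `precision := TN/(TN+FP)` (numerically the
specificity), `recall := TP/(TP+FN)` (the sensitivity) and
`F1 := p·r/(p+r)` without the factor of 2 — a perfect classifier scores
0.5. Only this literal reading reproduces all four published F1 values
(0.31/0.30/0.30/0.33) from their rows' sensitivity/specificity, so it is
retained as an explicit reproduction mode and never as the default for
new analyses. Two published Youden entries (0.23, 0.20) differ by 0.01
from their own rows' `sens+spec−1`, presumably rounding of unrounded
underlying values; the two self-consistent rows are used as checks and
the discrepancy is left as-is. Likewise the published table heading maps
"precision" to sensitivity while the formula TN/(TN+FP) is the
specificity; the contradiction is preserved in reproduction mode and
noted here rather than silently corrected.

## Time-series classification

Whole subjects (both eyes, every visit) are assigned to
train/validation/test so no subject straddles sets; the greedy seeded
assignment balances waveform counts toward the fractions
(0.44, 0.27, 0.29 — the published 258/161/172 waveform split) and keeps
each set's positive-label share within a tolerance (default ±0.05) of the
overall share, retrying with new subject orders as needed. Both eyes of a
subject are treated as independent examples within their set.

Classifiers operate on the raw 430-sample series; labels are encoded
ON_POS → +1, ON_NEG → −1.

- **1-NN DTW** — from-scratch dynamic program over monotone warping paths
  with steps {(1,0),(0,1),(1,1)} and local cost |x_i − y_j| (squared cost
  and z-normalization are config options, off by default), optional
  Sakoe–Chiba band; numba-compiled with a pure-Python fallback. Distance
  and vote ties resolve to the smallest training index.
- **Time series forest** — per tree, `round(√T)` random intervals
  (minimum length 3, start and length uniform), each summarized by mean,
  SD and OLS slope; trees minimize cross-entropy (the tree learner is
  scikit-learn's `DecisionTreeClassifier(criterion="log_loss")`; interval
  sampling and features are own code). Prediction is majority vote, even
  splits going to the negative class.
- **SVMs, random forest, gradient boosting** — scikit-learn backends with
  the published best-model hyperparameters as defaults: RBF SVM `C=1.5`,
  `gamma = 1/(n_features·var(X))`; RF 200 trees (Gini); GB 100 stages
  (binomial deviance); linear SVM hinge loss.
- **LSTM** — a NumPy implementation (stacked layers, full backpropagation
  through time, Adam), defaults 3 layers × 16 hidden units, dropout 0.6
  between layers, batch 6, learning rate 1e-3, 100 epochs. Inputs are
  standardized by the training set's global mean/SD and gradients clipped
  to norm 5 for stability; both are implementation choices, documented
  because they affect optimization, not the contract. Training is
  deterministic given the seed.

The harness trains each kind on the training set, selects among candidate
configurations by validation reproduction-mode F1 (the study names no
selection criterion; F1 is its headline metric), and touches the test set
exactly once. Test labels are read only at final evaluation — label access
goes through a single audited helper, and a test verifies no test-subject
label is read between the split and the end of tuning.

## Synthetic cohort generator

Each waveform is a sum of three Gaussian pulses gated to the
post-stimulus interval — a-wave (amplitude −2 µV, latency 15 ms, width
4 ms), b-wave (+10 µV, 32 ms, width 8 ms) and PhNR (negative, 72 ms,
width 25 ms) — plus a constant offset, a linear drift (per-recording
slope ~ N(0, 0.005 µV/ms)) and white noise (default SD 0.5 µV). Latencies
and the slow PhNR width reflect photopic flash-ERG morphology; the a/b
widths were chosen once so that component overlap stays small enough for
the extractor to recover the composite's landmarks (wider b-waves bury
the a-trough under the b-wave's rising edge).

The disease effect is planted in the PhNR component only. Per-group
trough amplitudes are calibrated to the clinical cohort: ON
−2.8 ± 1.5 µV with prevalence 0.57, controls −3.7 ± 1.8 µV. A subject's
two eyes share a latent PhNR drawn from a bivariate normal with
correlation 0.5 (clipped at 0 to respect the sign constraint), so the
exchangeable working-correlation assumption of the GEE layer holds by
construction at the eye level; repeated recordings of an eye share its
amplitudes and differ only in drift and noise.

Two forms of ground truth accompany each cohort: the planted component
parameters, and *feature-scale* truth computed from the continuous
noiseless composite on a dense 0.01 ms grid (`noiseless_feature_truth`).
The distinction matters because extracted features are functionals of the
waveform — b-amplitude is trough-to-peak, which exceeds the b pulse
height by the a-trough depth — so recovery studies compare against the
functional's true value, not the pulse height. A fast `simulate_truth_table`
path generates per-recording observed PhNR values
(latent + N(0, noise/√11), the noise transfer of the 11-point average)
without synthesizing waveforms; calibration studies that only exercise
the statistical layer use it to afford thousands of replicates.

What the generator does **not** emulate: asymmetric component shapes
(real ERG waves are skewed; the extractor only uses extrema, means and
latencies, so symmetric pulses suffice — a skewed option exists),
oscillatory potentials, flicker artifacts, electrode drift
nonlinearity, device filtering, or any b-wave/a-wave group effect
(options exist for sensitivity experiments). Passing tests therefore
demonstrate correctness of the analysis machinery under a faithful
covariance and effect-size structure, not clinical realism of the
waveform shape.

## Calibration results and known limitations

- **Type-I error**: the ON-status Wald test on null cohorts
  (109 subjects, both groups at the control distribution) rejects at
  ≈0.05 over 1,000 seeded replicates — nominal.
- **Power**: with the calibrated effect (gap 0.9 µV, SDs 1.5/1.8 µV,
  inter-eye correlation 0.5, 109 subjects ≈ 218 eyes), the Wald z is
  ≈ 0.9 / sqrt(1.5²(1+ρ)/(2·62) + 1.8²(1+ρ)/(2·47)) ≈ 3.2, i.e. true
  power ≈ 0.89 at α = 0.05; the measured rate over 200 replicates of the
  full simulate→extract→GEE path is 0.895. A single cohort at z ≈ 3.2
  quite plausibly yields p < 0.0005 (the median p is ≈ 1.4 × 10⁻³), but a
  ≥ 0.95 power requirement is not met by these study conditions and is
  reported honestly as unmet rather than met by weakening the planted
  conditions.
- **PhNR_min shrinkage** under full-record detrend (see above) means
  Table-scale group moments of *extracted* features sit nearer zero than
  the planted moments; calibration checks therefore target the planted
  values via the truth table.

## Problem sizes used by the test suite

Unit tests run cohorts of 8–40 subjects; calibration tests use
109 subjects (the clinical scale) with 1,000 fast-path null replicates
and 200 full-path power replicates; classifier sanity checks use 40
(separated cohort) and 150 (permutation null, prevalence 0.5 so the
chance band is centred) subjects, with the LSTM on a reduced epoch budget
in the permutation check. The DTW oracle enumerates all monotone warping
paths for every pair of series of length ≤ 5 over a 3-symbol alphabet
(131,769 pairs).
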