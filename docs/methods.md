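# Methods

## Signal model and preprocessing

Beat-by-beat AS observations arrive at the heart rate, i.e.
non-uniformly in time.  At 70–103 bpm the inter-beat variation of
interest lives in the 1–2 Hz band, so resampling at 10 Hz oversamples
the highest embedded frequency five-fold (versus the Nyquist factor of
2).  Resampling uses a natural cubic spline through the beat samples,
evaluated on the half-open grid `start + k/rate`, `k = 0 … L·rate − 1`;
for a 2000 s window at 10 Hz this is exactly 20,000 samples.  The
half-open convention was chosen to make the sample count exactly
`L·rate`; the maximum available lag is then 1999.9 s and "integrating
to 2000 s" means "to the end of the spectrum".  The spline interpolant
reproduces the beat values exactly at their timestamps, and round-trip
tests on band-limited sinusoids hold reconstruction error below 10⁻³
of the amplitude.

Window selection skips the first 300 s (patients settling in produce
motion artifacts early in a session) and then applies an automated
gate replacing visual screening: 30 s segments on a 10 s sliding grid
are flagged when the median absolute deviation of their values from
the series-wide median exceeds 5× the series-wide MAD; flagged
segments are merged and the earliest start from which a full window
avoids them is chosen.  A manual start override is kept for parity
with visual selection, and a series that cannot host any window at all
raises an insufficient-data error rather than being silently patched —
whole-session rejection mirrors how compromised sessions are handled
clinically.

## Coherence statistic

The autocorrelation uses the biased estimator (divide by N, not N−k)
on mean-subtracted data: this guarantees |r(k)| ≤ 1 and positive
semi-definiteness, at the cost of a (1 − k/N) taper at long lags.
Mean subtraction is required for the coefficients to oscillate around
zero rather than sit on a positive pedestal.  Computation is by FFT
with zero-padding to ≥ 2N (no circular aliasing); equivalence with the
direct lag-sum is enforced to 10⁻⁹ relative error in tests.  No
detrending beyond mean subtraction is applied by default; slow drift
therefore inflates long-lag coefficients, which is deliberate — drift
*is* low-frequency coherence under this statistic.

The discrete feature is Σ |r(k)| Δτ over lags in [100 s, 2000 s) with
Δτ = 0.1 s (rectangular rule).  The 100 s floor isolates the ~3 min
modulations from short-range correlation that every physiological
series has.  Upper bound of the statistic: the lag-range length
(1900 s); a pure cosine of period 200 s gives (2/π)·1900 ≈ 1209.6 s, a
useful scale anchor.  The first zero crossing of r (linear
interpolation between bracketing samples) is provided as a secondary,
weaker feature.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with a latent two-class truth for validation:

- **Beat trains**: heart rate follows a reflecting lag-1 random walk
  (step SD 1 bpm per beat) inside [70, 103] bpm, so every inter-beat
  interval respects the configured band.  No published HR dynamics
  exist for this setting; the walk is the simplest bounded process with
  realistic beat-to-beat correlation.
- **AS traces**: baseline 1.0 (arbitrary units — the AS numeric scale
  is device-arbitrary) plus a class-amplitude sinusoid of period 180 s
  with uniform random phase, plus stationary AR(1) noise (coefficient
  0.3, SD 0.35).  Severe amplitude 1.0, mild 0.2.  Optional square
  artifact bursts (10 s) are confined to the first 300 s.
- **Dose link**: dose = max(0, 160 + 500·amplitude + N(0, 220²)) mcg,
  rounded to the 100 mcg bolus size.  The link is a modeling invention
  (the true amplitude–dose relation is unobservable); its calibration
  gives a 50/50 cohort an expected mean ≈ 460 mcg and SD ≈ 297 mcg,
  and lets mild patients clip to zero dose, reproducing the existence
  of patients needing no vasopressor.  Parameters were fixed once from
  these closed-form moments.
- **Covariates**: pre-op systolic pressure ~ N(128.9, 19.14²) mmHg and
  binary comorbidities at obstetric-cohort prevalences, generated
  independently of dose, so covariate–dose correlations are null by
  construction.

What the generator does **not** emulate: real AS scale and drift,
respiratory or baroreflex rhythms, non-stationary modulation
envelopes, dose–class overlap driven by clinical judgment, and any
post-induction hemodynamics.  Passing tests therefore demonstrate that
the pipeline recovers the intended structure when it is present — not
that the clinical effect size is as large as the synthetic one.

## Classification assessment

Severe = dose strictly greater than the threshold (the at-threshold
tie goes to mild).  The score orientation is fixed a priori (higher
coherence ⇒ severe) rather than auto-oriented, which avoids optimistic
bias on null data.  AUC is the Mann–Whitney rank statistic with ties
half-credited; it equals the trapezoid area under the empirical ROC,
and the Youden maximum breaks ties toward higher specificity.
Correlations of baseline covariates with dose use Pearson (which is
the point-biserial convention for 0/1 covariates), two-sided
t-approximate p-values, no multiplicity correction; covariates without
variation are reported as "no positive patients" / "no variance"
rather than as numbers.

**Sample size.** `auc_sample_size` uses the Hanley–McNeil variance
with exponential-form Q1 = A/(2−A), Q2 = 2A²/(1+A).  Two framings are
implemented because the inputs (a margin *and* a power) overdetermine
a single formula:

- default, *precision with power*: smallest n with
  (z₁₋α/2 + z_power)·SE(A; n) ≤ margin.  All four arguments
  participate and n is monotone in each.  For (0.85, 0.025, 0.01,
  0.95, 1) this yields 4290 — pinning an AUC within ±0.025 genuinely
  requires cohorts of that order, since SE(AUC) at n ≈ 33 is ≈ 0.07.
- `null_auc=0.5`, *power against chance*: smallest n with
  z₁₋α·SE(0.5; n) + z_power·SE(A; n) ≤ A − 0.5 (margin unused).  For
  the same inputs this yields 34, the familiar "a few dozen patients"
  answer for *detecting* discrimination rather than estimating it.

The chosen variant is recorded in the result's `formula` field.

## Network protocol

Log-sigmoid on every layer including the single output node (binary
target 0/1; one output node is the minimal faithful architecture),
MSE loss, full-batch gradient descent (batch = sample size), learning
rate 0.01.  Weights initialize uniform on ±1/√fan_in, biases at zero.
Each run draws a random 0.7/0.15/0.15 split (validation and test sizes
floored, remainder to training: 45 → 33/6/6), retries the split if
training lacks a class, stops when validation MSE has not improved for
6 epochs (cap 1000), and restores the best-validation weights.
Backprop is verified against central finite differences (ε = 10⁻⁶,
relative error < 10⁻⁵) on randomized architectures.

Inputs are spectra block-averaged into 400 equal-width lag bins and
standardized per feature over the cohort; 400 bins keeps the input
width sane against a 45-sample cohort while preserving the modulation
structure (the paper-scale 20,000-dim input is configurable).
Ensembles report mean/SD/range of test errors and mean of per-run test
AUCs; a pooled ROC over concatenated test scores is also computed
since "ensemble ROC" is ambiguous between the two.  The run-count
convergence rule — SD(errors) ≤ 0.1 × error range, with a 1.5×
tolerance factor absorbing "approximately" — is reported, not
enforced.  The architecture sweep evaluates (nodes × depth × dose
threshold) cells with deterministic per-cell child seeds and emits
single-layer-minus-deeper difference surfaces (negative error
difference ⇒ deeper worse).

## Problem sizes and determinism

Default analyses use the 45-patient cohort, 100-run ensembles, and
20–30-run sweep cells; these sizes make every driver finish in seconds
to tens of seconds on one core while leaving ensemble aggregates
stable to ~0.02 in AUC.  All randomness flows from one master seed
through named/spawned child seeds (cohort, per-patient streams,
per-run streams, per-cell streams), so every artifact is reproducible
bit-for-bit; artifacts carry the config hash and seed in a header
comment.

## Known limitations

- The coherence statistic conflates oscillation, drift and artifact
  persistence; it is a severity *screen*, not a mechanism estimate.
- Dose-threshold labels inherit bolus quantization and dosing-practice
  noise; AUC against dose labels is systematically below AUC against
  the latent state, on synthetic and presumably real data alike.
- With 45 patients and 6-sample test sets, per-run NN AUCs are very
  coarse (multiples of 1/9 for a 3/3 split); only ensemble means are
  meaningful.
- The MLP deliberately omits momentum/Adam, regularization and
  dropout to stay faithful to the studied protocol.
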