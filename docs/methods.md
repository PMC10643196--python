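# Methods

This note documents the models implemented in `wristmets`, the parameters
that matter, and the numerical and design choices made where the published
methodology leaves details open.

## Signal model and preprocessing

Raw input is tri-axial wrist acceleration in units of g, nominally sampled
at 100 Hz. Time stamps must be strictly increasing with sample intervals
within ±10% of the nominal interval; larger gaps are rejected rather than
imputed, because the target devices log at a fixed rate and silent
imputation would corrupt the window statistics.

**Kalman smoothing.** Each axis is filtered independently with a scalar
local-level (random-walk) Kalman filter: state transition x_t = x_{t−1} + w,
w ~ N(0, q); observation z_t = x_t + v, v ~ N(0, r). Defaults q = 1e−4 g²,
r = 1e−2 g², prior mean = first observation, prior variance = r. These
defaults are declared, not estimated: they give a mild smoother (steady-state
gain ≈ 0.095, i.e. roughly a 20-sample exponential average) that reduces
sample-to-sample volatility without destroying the arm-swing oscillation.
All four parameters are overridable. Implementation note: the gain sequence
of this filter does not depend on the data, so after the gain converges
numerically the recursion is evaluated as a constant-coefficient first-order
IIR filter (`scipy.signal.lfilter`); a unit test pins the result to the
literal predict/update recursion at 1e−12.

**Gravity detrending.** Each smoothed axis has its trailing 5 s rolling mean
(inclusive of the current sample) subtracted; during the first 5 s the
window expands from one sample so no samples are dropped. The rolling mean
estimates the quasi-static gravity projection; the oscillatory movement
component averages to near zero over 5 s and passes through. The window
semantics (trailing, inclusive, expanding warm-up) are a declared
convention chosen to be causal and length-preserving.

**Vector magnitude.** VM = √(ax² + ay² + az²) after smoothing and
detrending, in that fixed order (smooth → detrend → VM). VM is invariant
under axis permutation (to floating-point reordering of the sum) and sign
flips (exactly).

## Windows and features

Windows are consecutive and non-overlapping, 60 s by default (10 and 30 s
supported); trailing partial windows are discarded, and windows never span
two treadmill bouts — the series is split at every change of the
speed/gait labels first. The *Mean* of a window is the arithmetic mean of
its VM samples.

Two feature sources coexist, mirroring how such pipelines are built in
practice: the nine ANN input statistics (mean, sd, max, min, p10, p25, p50,
p75, p90) are computed from the **raw** VM (vector magnitude of the
unfiltered axes), while the Mean used by the regression equations and the
walk/run cut-point comes from the **preprocessed** VM. Feature tables carry
both (`mean` … `p90` columns and `mean_detrended`). Percentiles use linear
interpolation between order statistics and the SD uses the n−1 denominator;
both conventions are declared for reproducibility rather than claimed to
match any external implementation.

Min–max normalization (x − x_min)/(x_max − x_min) is fitted on training
rows only and frozen; applying it to later data can therefore produce
values outside [0, 1], which triggers a warning but is deliberately not
clipped (clipping would silently hide covariate shift). Constant features
map to 0.

## Regression models

The three closed-form Mean→METs forms (linear, logarithmic with natural
log, cubic) ship with published wrist reference coefficients as immutable
models and can be refit by OLS on any (Mean, METs) table. R² = 1 − SSE/SST;
SEE = √(SSE/(n − p)) with p the coefficient count. Fits are pooled across
windows and subjects (repeated measures are not modelled); that matches how
the reference equations were produced, and a mixed-effects correction is
intentionally out of scope.

Predictions are never clamped; values outside a broad 0–25 METs band only
raise a warning, because the cubic form's known failure mode is silent
extrapolation: above its inflection point −c₂/(3c₃) — Mean ≈ 0.59 for the
reference cubic — predicted energy expenditure accelerates again.
`cubic_inflection` exposes that diagnostic.

## The ANN predictor

A 9-input, single-hidden-layer network with logistic-sigmoid hidden units
and a linear output predicts METs from the normalized feature vector. The
training loss is mean squared error plus weight_decay × (‖W₁‖² + ‖W₂‖²);
biases are not penalised. "Weight attenuation" is interpreted as this L2
penalty: the tuning grid 0.1–0.9 and RMSE-based selection are the standard
weight-decay recipe, and large decay demonstrably shrinks the weights to
zero and the predictions to the output bias (a property test asserts the
monotone shrinkage).

Optimisation is deterministic full-batch gradient descent with a fixed
learning rate (default 0.1, chosen as the largest rate that is stable
across the decay grid on the synthetic data; 0.2 already oscillates),
capped at 2000 iterations with an early stop when the loss improvement
falls below `tol` (1e−10). Initialisation: hidden weights seeded
uniform(−0.5, 0.5)/√(fan-in); the output layer starts at exactly zero with
output bias = mean(targets), so the initial network is the best constant
predictor and training can only improve on it — this also makes the
constant-target case an exact fixed point. Analytic gradients are verified
against central finite differences at 1e−6 relative error.

Hyperparameters are tuned by k-fold cross-validated RMSE over the
decay × hidden grid, refitting the normalizer inside each fold; ties prefer
fewer hidden neurons, then stronger decay. Tuning never touches a held-out
validation split. Published reference settings are hidden = 8 / decay = 0.8
for the pooled model, 9/0.8 for the walking sub-model and 4/0.7 for the
running sub-model; the exact optimiser, activation and initialisation
behind those published settings are unknown, so published RMSE values are
approximable, not bit-reproducible.

## Walk/run cut-point and the two-stage model

ROC analysis treats "run" as the positive class and thresholds the window
Mean; candidate thresholds are the midpoints between consecutive sorted
unique Means plus ∓∞ sentinels, TPR/FPR are exceedance probabilities, and
the AUC is the trapezoidal area — identical (to 1e−12, property-tested) to
the Mann–Whitney statistic with ties counted ½, and cross-checked against
scikit-learn's implementation.

The cut-point maximises the Youden index J = TPR − FPR. For separable data
every threshold inside the walk/run gap attains J = 1; the returned
threshold is the midpoint of the gap (maximum-margin choice, and the style
of choice consistent with published cut-points under AUC = 1). When tied
maximisers are not contiguous the tie resolves toward the larger
thresholds. The classification rule is strict: Mean > threshold → run, a
Mean exactly on the threshold → walk.

The two-stage model fits the cut-point and the two gait-specific ANNs on
the same training split (each sub-model with its own normalizer, on its own
gait stratum) and dispatches each window by its classified gait.
Predictions are exactly piecewise: restricted to windows classified as
walking they equal the walking ANN's predictions bit for bit.

## Evaluation

RMSE = √(mean((pred − meas)²)). Bias is implemented in both of the forms in
circulation — the relative formula mean((pred − meas)/meas) and the
absolute mean(pred − meas) — because the literature prints the relative
formula while discussing the result in METs; `relative` is the default and
every report labels its mode. Bland–Altman limits use the fixed 1.96
multiplier (not a small-sample t quantile) with the n−1 SD; points exactly
on a limit count as inside. The unit of analysis is the window, not the
subject. Per-speed rows report bias ± SD of the per-window bias terms,
labelled as SD. A pooling identity (count-weighted mean of per-speed
squared RMSEs equals the overall squared RMSE) is asserted as a report
self-check.

## Synthetic cohort

The generator emulates the treadmill validation protocol: 100 subjects
(70/30 modeling/validation split by subject, never by window), eight
4-minute bouts at 2–9 km/h, 100 Hz. Per axis the signal is a static gravity
projection plus an arm-swing sinusoid at the step frequency
f(v) = 0.8 + 0.25·v Hz, with amplitude amp_scale × 0.03·v g (walk) or
0.05·v g (run), axis phases 120° apart, plus white noise (sd 0.02 g).
Measured METs per 60 s window are an ACSM-style speed curve — walk
(0.1·v + 3.5)/3.5, run (0.2·v + 3.5)/3.5 with v in m/min — plus a
per-subject offset (sd 0.3 METs) and per-window noise (sd 0.4 METs), values
chosen so METs span ~2–11 and model RMSEs land in the 0.4–1.4 METs range
typical of treadmill validations.

Two structural choices matter. The amplitude jump between walking at
6 km/h (0.18·amp_scale g) and running at 7 km/h (0.35·amp_scale g) makes
walk and run window Means separable, as observed on real wrist data; the
between-subject amplitude factor is uniform on 0.85–1.15, a spread narrow
enough that separation holds across the whole cohort, not just within
subjects. And because the three axis phases are 120° apart, the detrended
VM of the sinusoid is nearly constant at amplitude·√1.5, so window Means
are tight around their per-speed values.

What the generator does **not** emulate: biomechanical gait waveforms,
harmonics, device-specific noise spectra, posture changes, rest periods, or
free-living activity. Passing the end-to-end tests therefore shows the
pipeline is correct and that the two-stage structure helps when gaits are
separable — it does not certify accuracy on real wrist data, and the
synthetic cut-point (~0.17–0.19) intentionally differs from any published
threshold, which is a property of the original cohort. On this synthetic
cohort only AUC = 1 and 100% held-out accuracy are reproducible properties.

## Problem sizes and determinism

Unit tests run on scaled-down cohorts (typically 6 subjects with the full
8-speed protocol); the end-to-end separation and model-ranking checks use
the full default 100-subject cohort. Every stochastic component (subject
profiles, sensor noise, METs noise, weight initialisation, fold
assignment) is driven by explicit integer seeds, and identical seeds give
bit-identical streams, features, and trained weights.

## Known limitations

- The Kalman defaults are a declared smoother, not parameters estimated
  from any device; heavier smoothing shifts the synthetic cut-point.
- Pooled OLS ignores within-subject correlation; reported SEs on refits are
  accordingly optimistic for clustered data.
- With the loss defined as MSE + decay·‖W‖², decay values near the top of
  the published grid (0.7–0.9) shrink these small networks almost to their
  output bias; the gait-specific models then behave like per-gait means,
  which is exactly why the two-stage split still beats a pooled network on
  separable data.
- The CLI's `simulate` writes full raw logs (~11 MB per subject at 100 Hz);
  use the in-memory `generate_dataset` when only feature tables are needed.
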