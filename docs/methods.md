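# Methods

This note documents the models, numerical choices and open design decisions
behind `decostress`, and what its synthetic-data tests do and do not show.

## HRV estimation

R-R series are validated (strictly positive intervals; values outside
200–3000 ms only raise a warning — no artifact or ectopic-beat filtering is
applied) and cut into non-overlapping windows of 256 consecutive beats;
trailing beats that do not fill a window are discarded rather than padded,
preserving the "consecutive beats" definition. Per window:

* mean R-R (ms);
* SDNN: sample standard deviation (N−1 denominator, standard HRV practice);
* RMSSD: √(mean of squared successive differences).

A recording-level value is the unweighted mean of its window values
(`summarize_recording`); computing the estimators once over the whole
recording is exposed as `whole_recording_features` since either aggregation
is defensible for a 30-minute record, and with ~256-beat stationarity they
differ little.

### Spectrum

The beat series is mean-removed and FFT'd as-is — i.e. treated as uniformly
sampled at the mean heart period, so bin k maps to k/(W·mean RR in s) Hz.
This "cycles per beat" convention is simple and exactly reproducible; it
compresses/stretches frequencies by at most the coefficient of variation of
the R-R series relative to true time. Cubic-spline resampling onto a uniform
grid (e.g. 4 Hz) is available via `compute_psd(..., resample_hz=4.0)` but is
not the default. No taper is applied (rectangular window) and only the mean
is removed, keeping the Parseval bookkeeping exact: one-sided bin powers are
scaled so their sum equals the window's population variance (checked to
1e-9 relative in tests).

Bands are VLF 0.01–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz, half-open [lo, hi)
so every bin belongs to exactly one band, with the top edge of HF inclusive.
A 256-beat window at 800 ms resolves ~0.0049 Hz at best, so the lower part
of VLF is below resolution; the spectrum records `min_resolvable_hz` and the
band is computed anyway. Normalized units divide by VLF+LF+HF (×100); band
*fractions* divide by SDNN², the total-power proxy (as recording length
grows, total spectral power and variance converge). An HF of exactly zero
makes LF/HF undefined; it is reported as NaN, never as infinity.

## Paired statistics

Differences post−pre are gated by Shapiro–Wilk at 0.05: normal-looking
differences use the paired t-test, the rest a sign-flip permutation test
whose statistic is the mean difference. The permutation p-value is two-sided
and includes the identity assignment; when 2ⁿ ≤ rounds all sign patterns are
enumerated (exact), otherwise 10,000 seeded Monte-Carlo draws are used with
an add-one correction so p is never 0. The gate and the statistic are
reproducible stand-ins — which variables the original analysis sent to each
branch is unknowable, so the gate is deterministic and documented.
Regressions are ordinary least squares with t-distributed slope tests; the
correlation matrix is pairwise-complete Pearson with
t = r·√((n−2)/(1−r²)). No multiple-testing correction is applied.

## The RBF network

All variables — the eight marker ratios *and* the SDNN-ratio response — are
min-max normalized per column to [0, 1]; the stored min/max allow exact
inversion, and predictions are reported denormalized. A constant column is
an error (its scale is undefined).

The model is ψ(x) = Σⱼ aⱼ·exp(−‖x−Mⱼ‖²/2σ²) + b with a single shared width

    σ = Dmax / √(2S),

the standard heuristic tying kernel width to centroid spacing (Dmax = max
pairwise centroid distance, S = number of centroids). A σ override is
available (`train_rbf(..., sigma_override=...)`). For S = 1 no pairwise
distance exists; the unit-hypercube diameter √n stands in for Dmax. A draw
with Dmax = 0 (probability ~0) is redrawn, capped at 100 redraws.

Weights solve the N×(S+1) design system θW = y in the least-squares sense.
The implementation is SVD-based minimum-norm least squares rather than the
literal (θᵀθ)⁻¹θᵀ — identical when the normal equations are invertible
(verified to 1e-6 against a normal-equation oracle on random instances) and
numerically stable when θ is near-singular, which Gaussian designs often
are; rank deficiency logs a warning.

Training draws S centroids uniformly in [0,1]ⁿ per trial and keeps the
lowest-training-RMSE model. Trial t uses the seed's spawn-key substream t,
so a trial's draw is independent of the total trial count and best-of-T
error is non-increasing in T under a fixed seed (tested). Default trial
counts: 10,000 for a single fit, 100 per split in resampling.

### Choosing S

The K-means within-cluster sum of squares WSⱼ (Lloyd's algorithm, 10
restarts, best objective) is computed for j = 1..S_max (default
min(10, N−1)) and a power law WSⱼ = WS₁·j^(−ε) is fitted by least squares
on the log-log scale with the intercept anchored at log WS₁. The selected S
is the smallest j ≥ 2 whose observed WSⱼ lies at or below the fitted curve;
j = 1 is excluded because the curve passes through it by construction, and
a near-flat decay (ε < 0.05) selects S = 1. This elbow rule is deliberately
isolated in `select_cluster_count`. Known limitation: on data with no
cluster structure (e.g. i.i.d. predictors) WS decays roughly linearly in j,
which is convex in log-log, so the observed curve stays above the anchored
power-law fit until large j and the rule selects a large S — a generous
basis count that can overfit small training sets (see "What the synthetic
tests show").

### Error scale

Model accuracy is RMSE of predicted vs observed SDNN ratio. Internally the
fit minimizes RMSE on the normalized response; because denormalization is
affine, the raw-scale RMSE is the normalized RMSE times the training
response range and the model ranking is identical. Results expose both:
`TrainResult.training_rmse` (normalized) and the `*_rmse_raw` fields
(SDNN-ratio scale). Comparisons against a noise level — itself defined on
the ratio scale — use the raw fields.

## Evaluation designs

* **In-sample** (`fit_in_sample`): train and score on all N rows; training
  and validation error coincide by construction.
* **Hold-out** (`fit_holdout`): seeded draw without replacement (default
  37 train / 10 validation at N = 47). Normalization min/max are computed on
  training rows only — no leakage; held-out predictors falling outside that
  range are clipped to [0, 1] with a logged warning rather than
  extrapolated (the Gaussian basis decays anyway, but clipping keeps ψ
  within its calibrated domain). `normalize_on="all"` reproduces the leaky
  alternative for comparison. The cluster count is re-selected on each
  training set.
* **Resampling** (`resampling_experiment`): the hold-out repeated over
  n_splits independent splits (each validation set is the complement of its
  training set), collecting both error distributions. Split seeds derive
  from one SeedSequence, so the experiment is reproducible and
  embarrassingly parallel in principle. Failed splits (e.g. a constant
  predictor column in a training subset) are excluded and counted.

## Synthetic data

`generate_cohort` draws the eight marker ratios i.i.d. log-normal
(location 0, scale 0.4 on the log scale — ratios of positive quantities are
right-skewed, with fold-changes up to several-fold, matching inflammatory
marker behavior). The SDNN ratio is 1 + f(normalized markers) + N(0,
noise_sd) with noise_sd defaulting to 0.05; f is by default a 3-centroid RBF
(in-model, so recovery tests are sharp), with linear and sinusoidal-mix
options to probe misspecification. If a draw crosses zero the whole response
column is shifted up (recorded in the ground truth); with the defaults this
never triggers. `generate_tachogram` builds RRᵢ = mean + Σ amp·sin(2πf·tᵢ) +
noise with tᵢ the actual cumulative time, validating positivity and Nyquist
constraints before generating.

### What the synthetic tests show — and do not

Passing tests show the estimators, solver and evaluation plumbing are
correct and that the pipeline recovers a smooth planted ratio→ratio mapping
at realistic noise (hold-out RMSE within twice the injected noise at
n = 200). They do not show that real post-decompression cohorts satisfy the
generator's assumptions: markers there are correlated (the generator draws
them independently), the true marker→HRV mapping need not be smooth or
low-dimensional, and real tachograms contain ectopic beats, trends and
respiratory modulation that the sinusoid generator omits. One consequence is
visible even in-silico: at 47 subjects with 37/10 splits and decay-curve
cluster selection (which picks S = 7–9 on unstructured predictors), the
best-of-100-trials fit overfits — mean validation error exceeds mean
training error by ~70–80% in the resampling experiment, a larger
generalization gap than a well-regularized small-cohort model would show.

## Problem sizes used

The bundled evaluation script (`scripts/acceptance.py`) runs the full
pipeline at a 47-subject cohort, 2,000 in-sample training trials, 100 trials
per split and 50 resampling splits, completing in seconds on one core; the
library defaults (10,000 trials, 500 splits) reproduce the same quantities
at higher Monte-Carlo resolution.
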