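# Methods

## Model and assumptions

The regression target is the tail-condensed transform of the raw log-scale
EGFR copy-number score (below).  A zero-mean GP prior with unit signal
variance and RBF kernel is placed on the latent function; observations add
i.i.d. Gaussian noise σ².  The zero-mean assumption is realized by centering
the targets with the training-fold mean (added back at prediction time)
rather than by fitting a mean function.  Because the kernel carries no
amplitude parameter, features are z-scored per column on the training fold so
that a single lengthscale ℓ is meaningful across heterogeneous texture
features; the same statistics standardize test and unlabeled samples.
Predictive variance is reported as the latent-function variance (observation
noise is *not* added): this is the quantity the one-sided z-test and the
SD-based prediction categories consume.

The transductive predictor conditions on the labeled set plus the test
sample's eight unlabeled image neighbors, using the closed forms given in
the README.  The printed block matrix for σ²_tran is implemented as the
symmetric joint covariance of [X_L; X_U] — the only reading that is positive
definite.  Unlabeled samples share the labeled model's hyperparameters and
standardization: one model is fitted, then augmented per test sample.  An
exploratory (non-gating) test also compares the closed forms against a
literal "combined dataset" GP trained on {X_L, Y_L} ∪ {X_U, Ŷ_U}; the two
constructions agree closely in the mean but are not asserted equal, since
their algebraic equivalence is an open question.

## Tunable parameters

| Parameter | Default | Units / scale | Why |
|---|---|---|---|
| lengthscale ℓ | fitted in [1e−2, 1e3] | standardized-feature distance | multi-start (5) L-BFGS-B on the log marginal likelihood with analytic gradients; first start from the median pairwise distance |
| noise variance σ² | fitted in [1e−6, 10] | transformed-CNV variance | same optimization; ties break to highest likelihood then smallest ℓ |
| diagonal jitter | 1e−10 | added to K + σ²I | Cholesky stability at near-duplicate rows; part of the model definition (oracles include it) |
| CNV cutoff | 3.5 | raw and transformed scale | amplification boundary; a fixed point of the transform |
| p cutoff | 0.05 | one-sided z-test | certain/interpolated boundary; p = 0.05 exactly counts as uncertain |
| SD cutoff | 0.40 | transformed-CNV SD | extrapolated vs border boundary; SD = 0.40 exactly is border.  The SD unit (transformed scale) is an assumption — the source material does not state it |
| GLCM gray levels | 16 | of the 0-255 range | finer quantization gives sparse matrices on 64-pixel windows; configurable |
| Gabor bank | (0.1..0.5, 0.1) | (cycles/pixel, frequency-domain σ) | 5 pairs × (mean, std) = 10 features closing the 56-feature budget; the bandwidth token is interpreted as the frequency-domain std of the Gaussian envelope (spatial σ = 1/(2πb)), which keeps kernels at window scale |
| selection tolerance | 1e−6 | criterion units | minimum improvement to accept a feature; max_features 20 |

## CNV transform

Values ≤ 3.5 pass through unchanged; values above map through
`t(v) = 3.5 + w·log(v − 2.5)/log(vmax − 2.5)` with `w = 3.5 − min(train)`,
so the amplified group is compressed to the wildtype group's width while
order and class membership are preserved exactly and 3.5 is a fixed point.
Only the transform's *properties* (order preservation, tail condensation,
width matching) are externally specified; this particular log family is a
compatible stand-in.  `vmax` and `w` come from the training fold only; test
values beyond `vmax` extrapolate through the same strictly increasing
formula (no leakage, no clipping).  Degenerate inputs: a single-class
training fold yields the identity transform, and a wildtype side collapsed
onto the cutoff falls back to unit width.

## Synthetic cohorts

The generator emulates the study conditions: 25 patients, 1–6 biopsies
each, 336 features, raw CNV in [1.876, 82.43] with a long amplified tail,
eight neighbors per sample at feature-wise correlation 0.9.  A monotone
latent `g(u) = u + 0.3 sin 2u + 0.2 u|u|` of the (standardized) informative
combination, plus a patient random intercept (sd = noise_sd/2) and sample
noise (noise_sd default 0.35), is warped onto the CNV scale: linear below
the class boundary (set at the empirical (1 − amplified_fraction) quantile,
default 0.4 amplified per the reported 30–45% prevalence of EGFR
amplification in GBM) and exponentially (`expm1(4w)/expm1(4)`) above it.
The signed-quadratic term replaces a plain quadratic so the latent is
strictly increasing, which makes the noise-free single-feature cohort an
exact monotone function of that feature — a property the tests rely on.
ROI stacks are smoothed Gaussian random fields whose smoothness differs by
class (σ = 1.3 wildtype vs 0.45 amplified).

What the generator does **not** emulate: the joint covariance of real
texture features (features are independent normals; real GLCM/Gabor
features are strongly collinear), MRI physics of any kind, spatial
autocorrelation between biopsies of one tumor beyond the patient intercept,
and label noise in the CNV calls.  Passing tests therefore demonstrate the
*mechanics* of the method — calibration of the z-test stratification,
variance dominance, selection behavior — not clinical performance; the
study's real-data accuracies require the original cohort and are out of
scope.

## Numerical choices

All solves use Cholesky factorizations of jittered covariance matrices;
matrices are never inverted explicitly.  Predictive variances are clipped
at zero after block solves (round-off can produce ~−1e−16).  Tiny negative
variances below −1e−10 raise instead of clipping.  Normalization of a
constant window maps to all zeros; first-order skewness/kurtosis of a
constant window are 0 by convention (bias-corrected sample moments
otherwise, excess kurtosis); degenerate GLCMs set Correlation, IMC1 and MCC
to 0.  Percentiles interpolate linearly.  Rounding in the 0-255 intensity
map is half-up, so the canonical midpoint example maps 127.5 → 128.
Forward selection breaks candidate ties toward the lowest feature index,
and the step-0 baselines are the constant training-mean predictor
(accuracy) and p = 0.5 per sample (uncertainty).

## Problem sizes

The bundled verification suites use: 100 random instances for the
closed-form oracle (N ≤ 30, d ≤ 5), 1000 for variance dominance (N_L ∈
[3,30], |X_U| ∈ [1,8], d ∈ [1,10]), 100 for KL convergence at offsets {1,
10, 100}·ℓ, 50 replicates of N = 200 for hyperparameter recovery, and 20
cohorts of ~95 samples for the end-to-end stratification study (evaluated
on the cohorts' informative features, decoupling the stratification
property from selection runtime).  Selection tests run on 6–10-patient
cohorts with ≤ 10 candidate features, mostly in fixed-hyperparameter fast
mode; full per-fold refitting is exercised on the smaller fixtures.

## Known limitations

* A single shared lengthscale (no ARD): with hundreds of raw features the
  GP cannot down-weight noise dimensions by itself — feature selection is
  doing that job, as in the modeled study design.
* The transductive pseudo-targets Ŷ_U enter μ_tran only through the printed
  closed form; no iteration / self-training refinement is performed.
* The 18+28+10 per-contrast feature split is an inference from the naming
  scheme and printed totals, configurable rather than canonical.
* Non-stationary or composite kernels, k-fold/LOOCV evaluation modes,
  backward elimination and multiple-testing correction across samples are
  deliberately out of scope.
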