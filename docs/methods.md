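# Methods

## Problem

Robotic evaluation of the hemiparetic arm produces trajectory recordings
(planar shoulder-elbow endpoint positions, wrist/forearm joint angles,
optional force channels).  The pipeline turns those recordings into
session-level metric vectors, relates them to four clinical scales —
FMA-UE (0–66), WMFT, Barthel Index (0–100) and MRC motor power — via
correlation-filtered linear and shallow-neural-network regression, and
evaluates each model by patient-wise cross-validated correlation.  The
trial data this analysis targets is gated; a synthetic-cohort generator
with full ground truth stands in for it, so every stage is testable
against known generating parameters.

## Macro metrics

Point-to-point attempts yield aim, duration, deviation, dwell time,
mean/peak speed, speed shape and dimensionless jerk (registry and
definitions in `metrics.md`).  Numerical choices:

* Derivatives are central differences on the timestamp grid (`np.gradient`
  handles non-uniform sampling; no fixed-rate assumption anywhere).  An
  optional Savitzky-Golay pass (default window 5, polyorder 3, applied
  only on uniform grids) precedes differentiation because third
  derivatives of measured data are noise-dominated.  Smoothed speed is
  clipped at zero.
* Jerk normalization: discrete movements use ∫j²dt · D⁵/A² with D the
  attempt duration and A its path length; the rhythmic variant uses
  ∫j²dt · D/v̄².  These are the two standard dimensionless conventions;
  both are invariant to amplitude and duration rescaling.  On a dense
  noise-free minimum-jerk reach the discrete value is 720 and speed shape
  is 8/15 — both used as analytic fixtures.
* Aim is measured at the first local speed maximum; deviation uses the RMS
  (not maximum) perpendicular distance, with a `deviation="max"` switch.
* Dwell uses 5% of the segment's peak speed inside the target tolerance
  radius, matching the segmentation convention of the file reader.
* Ellipse fitting for circle drawing is a direct least-squares conic fit
  (via scikit-image) applied to centred, RMS-scaled points — the raw conic
  solve is ill-conditioned far from the origin — with semi-axes scaled
  back and the major-axis orientation normalized to (−π/2, π/2].
* Two-link inverse kinematics uses the elbow-down branch throughout
  (right-arm convention; consistency within a session matters more than
  the branch).  Default arm: upper arm 0.31 m, forearm 0.34 m, shoulder
  0.45 m behind the workspace centre — generic adult values; the forward
  map of the recovered angles reproduces inputs to < 1e-9 m.

## Submovement model

Speed profiles are decomposed into support-bounded lognormal pulses.  A
pulse with onset `t0`, support duration `D` and amplitude `A` is, in
normalized support time τ = (t−t0)/D ∈ (0,1),

    v(t) = (A/D) · 1/(τ(1−τ)σ√(2π)) · exp(−(ln(τ/(1−τ)) − μ)²/(2σ²)),

a logit-normal density scaled to integrate exactly to A.  Support-bounding
constructions differ between published variants; this one was chosen over
a hard truncation of the plain lognormal because the truncated family is
not identifiable from sampled profiles — its shape depends on (D, μ) only
through ln D + μ away from the truncation point, so noise-free refits
recover μ with percent-level error at machine-zero residual.  The
logit-normal form decays smoothly to zero at both support ends, has a
closed-form normalizer, and makes all five parameters recoverable to
better than 1% from noise-free samples.  σ is bounded at 1.2 < √2, which
guarantees unimodality; the mode solves ln(τ/(1−τ)) = μ + σ²(2τ−1) and
moves earlier as μ decreases.

Decomposition is greedy matching pursuit with joint refitting: start with
one pulse initialized at the largest residual peak (duration from its full
width at half maximum, μ₀ = −0.2, σ₀ = 0.4), refit all parameters by
bounded nonlinear least squares (`scipy.optimize.least_squares`, trf), and
add pulses until the residual RMSE falls below `rmse_tol` (default 2%) of
the profile's peak speed or `max_n` (default 8) pulses are reached; up to
`restarts` (default 5) jittered re-runs follow a failed tolerance, all
seeded.  Bounds keep the optimizer off degenerate spikes: D ∈ [0.05 s,
segment span], A ∈ (0, 2·path length], σ ∈ [0.05, 1.2], μ ∈ [−2.5, 2.5].
Candidate models are accepted only when they do not worsen the residual,
so the residual history is non-increasing.  Micrometrics (count, mean
duration, overlap, peak, interpeak interval) follow; overlap and interpeak
need ≥ 2 pulses and are reported missing otherwise.

## Synthetic cohort

One latent impairment z ∈ [0,1] per patient (truncated normal, mean 0.6,
sd 0.22 — placing the emulated population's FMA-UE mean in the
mid-twenties), drifting across up to 4 sessions (−0.03 mean recovery per
later session, sd 0.02).  Defaults mirror the emulated study conditions:
82 patients, 4 sessions, 8 reach targets on a 14 cm circle, 80 pointing
movements per task, 60°×30° wrist target ellipse, ±30° forearm targets,
20 circle repetitions (4 conditions × 5), 5 force trials per direction,
200 Hz sampling.

Clinical scores are monotone links of z — linear for FMA-UE/WMFT/MRC,
sigmoid for BI (its well-known ceiling) — plus Gaussian observation noise
(sd 3–6 score units), clipping to the scale bounds and rounding to the
scale granularity.  Noise-free scores and all generating parameters are
carried in a `GroundTruth` object that is never fed to the pipeline.

Trajectory quality degrades with z through the recovery signatures the
submovement literature reports: submovement count per movement is
1 + Poisson(3z), pulse overlap shrinks with z, path curvature error and
isometric wander grow with z, resistance-task displacement and
per-direction shoulder force fall with z.  The generator is
phenomenological: no forward dynamics, no EMG, no measurement dropout, no
learning effects within a session.  Passing tests therefore demonstrate
that the pipeline recovers relationships of this generative form at trial
scale — not that the trial's effect sizes are reproduced.

A separate single-feature generator (`simulate_feature_cohort`) draws
(x, y) bivariate normal with an exact population correlation (or a
saturating logistic link for model-ordering experiments); it backs the
cross-validation calibration checks because its population R is known in
closed form.

## Feature selection and models

Selection keeps features with |R| > 0.5 against the target scale.  The
absolute value matters: worse-is-larger metrics (deviation, offset,
scatter) anti-correlate with the scales; a signed option exists.  When
nothing passes, a flagged top-k fallback is available (the BI-style case).
Mutually dependent selected features (pairwise |R| > 0.85 — the dependency
cutoff is a config, logged into the result) are reduced to one per
connected component, preferring an explicit keep-list (the
operationalization of "better interpretability"), else the strongest
correlate.  Selection is computed once on the full table by default, with
a per-fold option; correlations are pairwise-complete, and rows missing a
selected feature are dropped from modelling with a logged count.

Features are rescaled by their training-fold maxima; the target is
max-rescaled for the nonlinear model only.  The linear model is OLS with
an explicit rank check.  The nonlinear model is a multilayer perceptron
with one hidden layer of exactly 2 sigmoid units and a linear output,
trained by full-batch nonlinear least squares (Levenberg-Marquardt,
tolerance 1e-8, cap 2000 iterations-worth of evaluations) from 10 seeded
random initializations, keeping the best training RMSE — small enough to
be trained exactly, multi-start handles local minima, and identical seeds
give identical weights.

Cross-validation samples patients, not rows (k = 4): all of a patient's
sessions stay together, eliminating identity leakage.  Fold sizes differ
by at most one patient, assigned in seeded shuffled order.  Per fold, a
Mann-Whitney two-sided test compares train vs test target distributions;
any p < 0.05 redraws the entire partition (up to 20 times, then a warning).
The reported R is the mean of the four test-fold correlations (the pooled
prediction R is carried as a secondary), and its p-value comes from the
t-transform of R at the pooled test sample size — a documented choice, as
is treating severity strata (e.g. FMA-UE 1–38 vs 39–66) by the session
score with an admission-score option.

VIF_j = 1/(1−R_j²) from an explicit OLS of each feature on the rest; R_j²
is clipped at 1−1e-12 and flagged "effectively infinite" when clipped,
with VIF > 10 flagged as strong multicollinearity.

## Reporting

Correlation strengths are labelled very weak (≤ 0.30), weak (0.31–0.50),
moderate (0.51–0.70) and strong (0.71–1.0) on |R|; gap values (e.g. 0.305)
fall to the lower bin.  The results grid is scale × device
(shoulder-elbow, wrist, both = joint refit of the union of selected
features) × model, rendered deterministically to markdown/JSON with
seeds and configuration in the provenance block; heatmaps are the
feature × scale and scale × scale Pearson matrices, written as CSV next to
the raster.

## Problem sizes in the validation runs

The acceptance script and test suite use reduced but statistically
adequate sizes chosen once: 100-case seeded suites for decomposition
recovery, 1000 seeds for fold integrity and balance calibration, 100
replications (80 patients × 3 sessions) for cross-validation calibration,
10 cohorts for the model-ordering property, and a 16-patient × 2-session
full-pipeline demonstration with 6 reaches per pointing task.  Two
baseline sessions are kept as distinct rows (a `merge_baselines` choice is
left to the caller when building tables).

## Known limitations

* The generator's effect sizes are configuration, not estimates; headline
  correlations from the emulated trial are not reproducible from synthetic
  data and are not claimed.
* Segmentation from target cues uses a single speed-threshold convention;
  pathological tremor profiles may need explicit segment columns.
* The forearm task is 1-D, so its `deviation` is identically zero.
* WMFT and MRC scoring variants differ across protocols; their maxima are
  configuration (75 and 80 by default) and the report labels the scale as
  configured.
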