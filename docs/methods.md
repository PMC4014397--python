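# Methods

This note documents the models, estimators, simulator and numerical
choices behind `superpose`, in the order the pipeline applies them.

## From raw wells to activity curves

**Inputs.** A wide CSV per plate (one `time_min` column; `<well>.od` and
`<well>.fluo` columns) plus a plate map (`well, promoter, conditions, day,
is_control`). Condition sets are canonicalized to sorted labels, so
`B+A` and `A+B` are the same condition. One promoterless-vector well per
plate supplies the fluorescence background; its (interpolated) signal is
subtracted from every reporter well. Negative post-subtraction values are
kept by default so the derivative stage sees unbiased noise
(`clip_negative_fluo` floors them at zero). OD is not blank-corrected by
default — the assay description we reconstruct does not mention OD
blanking — and no optional blank is applied unless configured.

**Promoter activity.** P(t) = slope of fluorescence over a centered
sliding window, by ordinary least squares, divided by the mean OD over the
same window. The default window is 17 samples (~136 min at 8-min
sampling); endpoints where a full window does not fit are dropped. The
window is a config knob: 5–30 give the same qualitative conclusions, and
the suite exercises 5 and 17. Units: fluorescence · OD⁻¹ · min⁻¹, with
both fluorescence and OD in instrument units.

**Growth rate.** The same window regression applied to ln OD; windows
containing non-positive OD emit missing points.

**Generation axis.** g(t) = log2(OD(t)/OD(t₀)). OD is smoothed in the
*log* domain (window-regression fit of ln OD evaluated at the window
center): batch-growth OD is locally exponential, and arithmetic window
means of an exponential overshoot the center value by a growth-rate-
dependent factor, which would shift conditions against each other by up to
half a generation. The origin t₀ is the first sample, with OD(t₀) taken
from the first-window regression evaluated at t₀. This matters: the first
*retained window center* sits at a different absolute generation count in
fast and slow media (~0.7–1.4 generations at the default window), and an
origin there would break the cross-condition alignment the mixture model
needs. A cumulative maximum enforces monotonicity under OD noise, because
interpolation onto the shared grid requires a monotone axis. The axis is
invariant to the OD unit.

**Shared grid.** All curves are linearly interpolated onto one uniform
grid of 100 points spanning the *intersection* of their generation ranges
— never the union, so no curve is ever extrapolated. Missing points are
dropped before interpolation.

## Per-promoter principal shapes

For each promoter, replicate days are averaged per condition set and the
conditions × grid matrix is decomposed by an **un-centered** SVD. The
un-centered form is the one matching the mixture model: a measured curve
is a plain linear combination of the shape curves with no mean offset,
and a one-shape promoter is exactly "same shape, different amplitude".
`center=True` switches to conventional mean-centered PCA for comparison;
the choice is recorded in the output metadata. Variance fractions are
σᵢ²/Σσⱼ². The randomized null permutes entries within each grid column
across conditions (preserving each grid point's marginal), recomputing the
two-component variance fraction per shuffle; the permutation is seeded.
The leading shape is compared with the mean instantaneous-growth-rate
curve by squared Pearson correlation (sign-free, so the SVD sign
ambiguity is immaterial).

## Mixture fits

All fits operate on day-averaged curves over the shared grid.

- **Unconstrained (errors-in-variables).** All curves — target and
  singles — are treated as equally noisy. The weights are read off the
  right singular vector of the smallest singular value of the stacked
  [singles | target] matrix, renormalized so the target coefficient is −1.
  A condition number of the singles matrix above 30 (the standard
  regression-diagnostics bound for serious collinearity) records a
  warning in the fit metadata: TLS weights are ratio-like and blow up on
  near-collinear singles, which here occur *by construction* whenever a
  promoter's dynamics is effectively rank 1 across conditions. For the
  same reason, summaries of the unconstrained weight sums use the median
  for location; the mean of a heavy-tailed ratio statistic is unstable.
- **Linear superposition.** Least squares subject to wᵢ ≥ 0, Σwᵢ = 1.
  Pairs reduce to a closed-form projection of the 1-D optimum onto [0,1].
  Larger cocktails are solved exactly by active-set enumeration: every
  support gives a small KKT system, the best feasible solution wins, ties
  break toward smaller supports. Deterministic, no random starts;
  practical up to ~16 singles (the study design needs 4).
- **Multiplicative.** ln(target) regressed on ln(singles) with the same
  simplex constraint — the target is modelled as a weighted geometric
  mean. Curves are floored at 1e-6 × their maximum before taking logs;
  the fit error is evaluated on the original linear scale.

**Fit error.** relative error = ‖fit − measured‖₂ / ‖measured‖₂ (a
mean-absolute variant is available; outputs state which was used). Two
figures are reported: the error against the day-averaged curve (what the
optimizer minimized) and the mean error against the individual
replicate-day curves. The second is the figure comparable to the
day-to-day noise floor — amplitude noise that averages out across days
still separates the fit from any single day — and is the headline
"mean fit error" in the evaluation summary.

**Model comparison.** AIC = n·ln(RSS/n) + 2k under a Gaussian likelihood
with unknown common variance; k counts free weight parameters (N−1 on the
simplex, N unconstrained). Ties break toward fewer parameters. With the
sum-to-one constraint true in the generating process and iid point noise,
the likelihood-ratio statistic of the constraint is ~χ²₁, so the
superposition model wins the comparison in about 84% of cases — the
"preferred in most conditions" regime.

## Predicting cocktails from pairs

An N-cocktail decomposes N ways as (N−1)-cocktail + one supplement; if
every decomposition obeys superposition and they agree, then
w_i = (N−2)/(Σ_{j≠i} 1/w_i^(≠j) − 1). The formula is exact whenever the
lower-order weights are restrictions of one simplex point
(w_i^(≠j) = w*_i/(1−w*_j)); the suite verifies this identity over
thousands of random simplex points. Non-positive lower-order weights
propagate to zero (a flag instead floors them at 1e-6, for use with
unconstrained fits); raw predictions are clipped to [0,1] and renormalized.
Pairs predict all triplets; predicted triplets predict the quadruplet.
Predicted dynamics is Σ wᵢ Pᵢ on the shared grid.

## Evaluation

- **Day-to-day error:** mean over replicate pairs of the symmetric mean of
  the two one-way relative errors (the L2-ratio metric is asymmetric in
  its denominator).
- **Exemplar baseline:** predicting condition X by each other measured
  curve of the same promoter, averaged exhaustively over exemplars (with
  15 measured conditions, exactly 14 errors) — deterministic, the limit of
  the random-exemplar construction.
- **Violation flagging:** a promoter is flagged when its best linear-model
  relative error for some cocktail exceeds a threshold (default 0.2).
  Flagging uses the simplex-constrained fits: on rank-2 promoters the
  unconstrained TLS can reproduce even switch-like dynamics with weights
  of ±10–20, so "best linear combination" taken over TLS fits would hide
  exactly the violations of interest. The detection tests use the 0.3 bar,
  which cleanly separates the planted violator (error ~0.7) from the
  honest-fit tail (a few percent of good fits exceed 0.2 at study noise).

## The synthetic-data generator

The generator emulates the study design: 4 supplements, all 15
combinations, 4 replicate days, 96-well plates with one background well
each, ~8-min sampling, logistic growth through ~6 generations to a final
OD of ~0.15, stationary phase reached between 8 and 22 hours (doubling
times drawn from 45–95 min per condition set).

**Ground truth.** Each promoter's activity lives in the span of one or
two latent shapes on the generation axis. Shape 1 is the logistic
growth-rate profile 1 − 2^(g−G) (so the leading principal shape tracks
growth rate by construction); shape 2 is a Gaussian bump (width 0.8
generations) at a promoter-specific position. A third of promoters load
on shape 1 only — amplitude-only variation across conditions. Two-shape
promoters draw the bump loading as a per-condition *share* (uniform on
0.05–0.85) of the growth-shape loading in curve-norm terms: shape change
across conditions is their defining property, and it keeps the
single-condition curves well-conditioned for weight recovery. Mixture
weights per cocktail are restrictions of one master simplex point per
promoter (flat Dirichlet, pulled 10% toward the center so every weight is
identifiable), which makes the weight hierarchy self-consistent — the
prediction formula's premise holds exactly in truth. Mixing happens at the
activity level on the generation axis, the model's own domain, and is then
pushed through growth and GFP rendering; this is the construction under
which the analysis pipeline can be exactly correct, which is what makes
recovery tests meaningful. Violator promoters get switch-like (diauxie-
style) dynamics in one designated pair: low activity before a switch
generation (~3), high after, with a 0.25-generation sigmoid — dynamics no
weighted average of their smooth single-condition curves can reproduce.

**Rendering.** OD follows the logistic solution per condition; GFP
integrates dG/dt = activity·OD by the trapezoid rule on the sampling
grid; a constant background (100 units) plus Gaussian per-timepoint noise
(0.5% of the well's signal range) is added to fluorescence, and 1%
multiplicative noise to OD. Replicate days multiply each well's activity
by a log-normal factor with total σ = 0.14 — the study-scale day-to-day
error — split into a component shared by all conditions of a promoter on
a given day (2/3 of the variance: inoculum and instrument state) and a
condition-specific remainder (1/3: media preparation, well effects). The
split matters: were the whole σ = 0.14 independent per curve, the
amplitude ratio between a day-averaged target and its singles would put a
floor of ~0.11 on the median pair-weight recovery error, contradicting
what the pipeline is expected to recover; with the realistic shared
component the shared part cancels in the fits and recovery lands near
0.08 while the measured day-to-day error stays ~0.16.

**What the simulator does not model** (and what passing tests therefore do
not show about real data): transcription/translation mechanisms, GFP
maturation kinetics, plate-position and evaporation effects, lag-phase
heterogeneity, and shape noise that does not factor into amplitude ×
latent-shape form. In particular, real promoters need not have exactly
low-rank dynamics, and real day-to-day variation may distort curve shapes,
not just amplitudes — both would degrade weight recovery relative to the
synthetic figures.

## Numerical choices and degenerate inputs

- Sliding-window regression handles non-uniform sampling; NaNs propagate
  to their windows and are dropped before interpolation.
- The TLS solver falls back to ordinary least squares if the target
  coefficient of the smallest singular vector vanishes (|v| < 1e-14).
- The simplex active-set enumeration tolerates singular KKT systems via
  least-squares solves; an all-infeasible enumeration (numerically
  pathological) returns uniform weights.
- AIC floors RSS at 1e-300 to keep the log finite on exact fits.
- Sample (n−1) standard deviations are used throughout.
- Zero-variance inputs to the growth correlation return NaN (undefined),
  not an error; all-zero measured curves are an error for relative error.
- Seeds: one integer seed drives truth generation; rendering derives its
  stream from seed+1 in the pipeline, so truth and noise are independently
  reproducible.

## Default problem sizes

The shipped defaults (20 promoters, 15 condition sets, 4 days, 100-point
grid) keep a full pipeline run around one second; the recovery studies in
the acceptance script use 200 promoters (singles + pairs) and complete in
a few seconds. These sizes were chosen to make the statistics stable at
interactive runtimes; all of them scale linearly in wells × timepoints
through the config.
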