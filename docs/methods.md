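# Methods

This note documents the models, the numerical choices, and the design
decisions behind the package, and what the synthetic-data validation
does and does not establish.

## Behavioral mixture model

Reports live on the hue circle (radians in [0, 2π); the stimulus grid
is 64 uniform points k·2π/64). Errors are wrapped differences in
(−π, π]. The per-trial report density is a three-component mixture:
correct (wrapped normal around the target t), swap (wrapped normal
around the distractor d, same dispersion σ), and guess (uniform,
1/2π). The wrapped normal is a truncated wrap sum over offsets k·2π
with |k| ≤ 3, whose truncation error is below 1e-12 for σ ≤ 1 rad; for
larger dispersions the sum widens automatically (k_max ≈ 4σ/2π), which
matters only in flat-likelihood limiting cases.

Sessions are pooled hierarchically. Session mixture probabilities are
softmax transforms of logits (w_swap_i, w_guess_i) with the correct
component as the zero reference; logits are drawn from animal-level
normals N(w_type, s_type). Priors: N(0, 1) on the hyper means; a
normal(1, 3) truncated at zero on the hyper SDs (a location-zero
half-normal with scale 3 is available via `sd_prior="half-normal"` —
the two readings differ negligibly on the validation data); an
independent half-normal with 1 rad scale on each session σ (a prior the
source analyses leave unspecified; configurable). σ is not pooled
across sessions.

Sampling uses the package's Hamiltonian Monte Carlo engine (below) in
an unconstrained parameterization: SDs on the log scale with Jacobian
terms, session logits *non-centered* (w_type_i = w_type + s_type·z_i,
z_i ~ N(0,1)), which removes the funnel geometry that otherwise
degrades gradient-based samplers when s_type is small. Default budget:
4 chains × (500 warmup + 500 samples). A MAP path (`method="map"`,
L-BFGS on the same posterior) serves fast runs; the MCMC path is
canonical.

Per-trial response-type posteriors follow Bayes' rule; with a full
posterior the per-draw probabilities are averaged over draws rather
than plugged in at the posterior mean (the two differ by < 0.05 on the
validation fixtures, but draw averaging is exact).

## Neural preprocessing

Units silent (zero per-trial total count in the analysis epoch) for 50
or more consecutive trials are excluded. Remaining contiguous zero runs
are masked and imputed from the five nearest-neighbor trials by
nan-aware Euclidean population distance (sklearn's KNNImputer, which
ignores the masked unit in the metric). Each unit is z-scored (SD floor
1e-8), PCA retains the smallest dimension count reaching 95% variance,
and — on the mixture-model path only — each retained dimension is
z-scored again so the model's noise priors see unit-scale data. In
cross-validated analyses all transform statistics come from training
trials only; a regression test asserts bit-identical pipelines when
test trials are perturbed.

## Encoding models and prototypes

Colors enter through a periodic B-spline basis with K uniform knots
(default K = 5, piecewise-linear; K ∈ {4,5,6} and quadratic splines are
supported). The basis is a partition of unity, nonnegative, and
periodic. The pre-cue model is linear in both colors with no intercept
(the z-score centers the data); the post-cue model has role-specific
weight matrices for each color as target or distractor plus
cue-specific intercepts, with b_1 paired to "upper cued" (the pairing
is a label convention; results are invariant to it). Noise is diagonal
Gaussian per dimension — no full covariance is fit.

Hypothesis prototypes are model means at counterfactual assignments:
misbound/misselected colors swap the two colors' roles; the
misinterpreted cue flips the cue (an involution); the reported-guess
prototype substitutes the reported color for the target-role color and
leaves the distractor unchanged. Ridge regression (default λ = 1 on
the z-scored scale) provides the two-stage encoder fits used by the
cross-validated analyses.

## Neural mixture model

Per trial, activity is a mixture of diagonal-Gaussian components at the
prototypes, with weights gated by the trial's *fixed* behavioral type
posteriors; the free scalars are p_misbind and p_resp (first delay) or
p_selection, p_cue, p_resp (second delay, with p_selection + p_cue ≤ 1).
The accumulated nominal weight is
p_C = p_correct + p_swap(1 − alternatives) + p_guess(1 − p_resp).
Mixture scalars are per-session constants. Everything — encoder
weights, noise SDs, scalars — is fit simultaneously by HMC; the
log-likelihood uses log-sum-exp and the gradients are analytic
(responsibility-weighted regression sums).

Two numerical choices matter here:

* **Whitened weight coordinates.** Because the spline basis sums to 1,
  block sums of the weight matrices are exactly collinear with the
  intercepts, leaving flat ridges in the raw weight posterior that a
  diagonal mass matrix cannot traverse. Weights are therefore sampled
  as φ = θL, where L is the Cholesky factor of the gate-weighted design
  Gram (ridge 0.01); the likelihood geometry becomes near-isotropic.
* **Prior.** φ receives a standard-normal prior — a unit-information
  ridge on the natural weights. With double-z-scored activity the
  natural weights are order one, so this is weakly informative while
  keeping the posterior well conditioned; a much wider prior scale
  (e.g. 10) leaves near-unidentified directions whose slow exploration
  shows up directly as chain-level convergence failures. Noise SDs get
  half-normal(10) priors on the log scale; mixture scalars get uniform
  priors via logit/stick-breaking reparameterizations with Jacobians.

Identifiability: when no trial has positive swap posterior the scalars
are unidentifiable; the fit warns explicitly and their posteriors
reproduce the prior (verified by a Kolmogorov–Smirnov test).

The optional hierarchical mode shares encoder weights across task types
(retrospective / prospective / single-stimulus): per-type weights are
non-centered normal deviations around a shared mean with per-entry SDs
(half-normal hyperpriors), all in the whitened coordinates. Single-
stimulus trials contribute through the same design with the missing
color's columns zeroed. In the prospective task the same delay-2
likelihood applies with relabeled semantics (its selection slot plays
the role of misbinding, its cue slot the role of selection).

## Cross-validated analyses

**Projection.** The anchored index
x = (r̄_A − r̄_B)·(r − r̄_B)/‖r̄_A − r̄_B‖² is exactly 0/1 at the
prototypes; the unanchored variant ((r̄_A − r̄_B)·r/‖·‖²) differs only by
a per-trial-pair offset and is available behind a flag. Likely-correct
(p_correct > 0.3) trials are scored leave-one-out — the encoder (and,
when requested, the preprocessing) is refit per fold — and likely-swap
(p_swap > 0.3) trials are scored in every fold and averaged. Trials
whose colors are closer than π/4 are excluded. The class difference
carries a bootstrap 95% CI (resampling trials, 1000 draws).

**Cue decoding.** L2 logistic regression with balanced class weights;
accuracy on likely-correct trials (p_correct > 0.6) by stratified
5-fold CV; the generalization gap is swap-trial accuracy
(p_swap > 0.4) minus that baseline.

**Distances.** For a pair of hypothesized representations, trials match
when their conditions — mapped through the hypothesis relabeling —
agree exactly on the cue and within one bin of an 8-bin circular color
partition. For each qualifying trial pair, v_A is the difference of
the two trials' activities and v_B the difference of the two matched
group means with the pair excluded; v_A·v_B is an unbiased (possibly
negative) estimate of the squared Euclidean separation. Session
matrices average across sessions with a simple mean (pair-count
weighting behind a flag). For display and MDS, distances are
sqrt(max(cell, 0)); classical (Torgerson) MDS embeds the three points,
exactly when the floored distances are metric, with a warning
otherwise.

## HMC engine

Leapfrog HMC with a jittered number of steps (uniform on
[max_leapfrog/2, max_leapfrog]), dual-averaging step-size adaptation to
a 0.85 target acceptance, and a diagonal mass matrix initialized from
the negative-Hessian diagonal at the MAP (central differences of the
analytic gradient) and re-estimated twice during warmup from draw
variances. Chains start at the MAP plus scaled jitter. Convergence is
summarized by the split-chain Gelman–Rubin statistic (cross-checked
against arviz's rank-normalized version in the tests) and bulk ESS via
arviz. Divergences (energy error > 1000) are counted and reported.

## Synthetic generator

The generator is the package's specification of the data it claims to
analyse. Stimuli: two colors independently uniform on the 64-point
grid; cue Bernoulli(0.5); task types per a configurable mix (default
all-retrospective; single-stimulus trials carry only the cued color).
Behavior: session parameters from the hierarchical prior (defaults
w_swap = −1.8, w_guess = −1.5, s = 0.3 — about 12% swaps and 14%
guesses — σ = 0.35 rad, matching the recovery conditions the package is
validated under); single-stimulus trials renormalize to
correct-vs-guess. Neural activity: ground-truth spline encoders with
Gaussian weights, scaled so the median nominal-vs-swapped prototype
separation is 2 per-unit noise SDs (a d′ ≈ 2 regime; configurable or
disableable); mechanism labels on swap trials (misbind shows the
swapped representation already in delay 1; misselect and miscue only
after the cue; "none" is the null with no neural signature); guess
trials carry the reported-color mean with probability p_resp_true
(default 0.5). Counts are rounded rectified rates around a baseline of
20 with noise SD 2 — the analyses z-score, so the discretization law is
not critical, only documented and seed-stable.

What passing recovery tests shows: the estimators are consistent and
calibrated *under the model's own assumptions* (diagonal Gaussian
noise, linear spline tuning, stationary weights). Real recordings
violate these in known ways — Poisson-like count noise, non-stationary
firing, correlated noise — so recovery here bounds implementation
correctness, not biological validity.

## Validation conditions and problem sizes

The recovery suite fixes: 10 sessions × 600 trials for the behavioral
hierarchy (posterior-mean p_swap within ±0.04 of truth for ≥80% of
sessions; every r-hat rounding to ≤1.01); one 500-trial × 60-unit
session for the neural mixture, fit in a 24-dimension post-PCA space
(p_selection and p_cue within ±0.15; null generator below 0.25
total). The 24-dimension cap is the package's fast-inference tier: on
this generator the extra PCA dimensions past ~24 carry mostly noise and
leave the scalar posteriors unchanged while slowing sampling. Decile
calibration of trial posteriors is checked at ±0.10 in every decile
whose binomial standard error is at most half that tolerance (~100
trials), so the check is never noise-dominated.

## Known limitations

* The neural mixture's weight r-hats can sit above the scalars' (the
  whitening is approximate where responsibilities differ from their
  gate-weighted average); the scientific scalars converge first and
  their diagnostics are reported separately.
* The imputation log records runs, not a full provenance of donor
  trials.
* Sliding-window analyses require window edges aligned to bin edges.
* The MAP tier underestimates hierarchical shrinkage relative to the
  posterior mean (mode vs mean of the SD hyperparameters); recovery
  tolerances are only claimed for the MCMC tier.
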