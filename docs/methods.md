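# Methods

## The model

`botclass` fits a two-class mixture to an N × p matrix of questionnaire
responses. Class 1 ("attentive respondents") follows a confirmatory factor
model with simple structure: for item *j* mapped to factor *k(j)*,

    g(E[y_ij | C_i = 1]) = τ_j1 + λ_j η_ik(j),      η_i ~ MVN(0, Φ),

with identity link and normal residuals (variance σ²_j1) for continuous
items, logit/Bernoulli for binary items and log/Poisson for counts. Class 2
("bots") is intercept-only: g(E[y_ij | C_i = 2]) = τ_j2, with its own
dispersion σ²_j2 in the continuous family. Because class 2 has no loadings
and never references the factor scores, the two classes cannot exchange roles
by permuting parameters — the mixture is structurally identified.

Class membership is predicted from two person-level indices through a
logistic model,

    P(C_i = 1 | ϒ1_i, ϒ2_i) = expit(β0 + β1 ϒ1_i + β2 ϒ2_i),

where

* **ϒ1** (person-fit) is −2·(ll_i(μ, Σ) − ll_i(ȳ, S)): the respondent's
  multivariate-normal log-likelihood under the implied moments of a
  preliminary maximum-likelihood CFA, relative to the saturated sample
  moments;
* **ϒ2** (variability) is the respondent's sample variance across the items
  of each factor, averaged over factors. Content-driven responses within a
  factor are similar; uniform random responses are not (expected value
  35/12 ≈ 2.92 on a 6-point scale versus well below 1 for reliable scales).

Identification: factor means are fixed at 0 and the first loading per factor
at 1; Φ is a free covariance matrix.

## Priors

Weakly informative defaults, all overridable through `PriorSettings`:
τ_jc ~ N(0, 1); free loadings λ_j ~ N(0, 1) truncated to [0, ∞) (all items
must therefore be keyed in the same direction — the reader recodes
reverse-worded items first); Φ⁻¹ ~ Wishart(I_m, m) (rate parameterization);
β_r ~ N(0, 10); residual precisions σ⁻²_jc ~ Gamma(9, 4). The truncated
loading prior and the Gamma(9, 4) precision prior presume item scales with
variance of order one (Likert codes qualify); the β prior is calibrated to
z-scored indices, which is why the indices are standardized by default
(a flag disables this).

## Estimation

Posterior sampling is by Markov chain Monte Carlo written for this model
(defaults: 3 chains × 12,000 iterations, first 6,000 discarded). For the
continuous family the kernel is a blocked Gibbs sampler:

* class indicators C_i are drawn with the factor scores integrated out of the
  class-1 likelihood (the marginal MVN with covariance ΛΦΛ′ + diag σ²₁),
  which also yields the Rao-Blackwellized per-person bot probability that is
  averaged over kept draws;
* factor scores, loadings (truncated normal), residual precisions (gamma) and
  Φ⁻¹ (Wishart via Bartlett) follow exact conditionals;
* the class-1 intercepts τ₁ are drawn from their *collapsed* conditional —
  Gaussian and conjugate in the factor-score-marginal model. Conditional on
  sampled factor scores, τ₁ rides a flat ridge against the mean factor score
  and mixes very slowly; the collapsed draw makes it effectively independent
  across sweeps;
* β uses an adaptive random-walk Metropolis step (Haario-style covariance
  adaptation during burn-in only, three inner proposals per sweep);
* two extra marginal Metropolis moves on Φ with the factor scores integrated
  out, plus one multiplicative "scale move" per factor that rescales
  (φ_kk, φ_kl, λ_j∈k) jointly along the scale ridge created by fixing the
  scaling indicator. One-at-a-time conjugate updates cross that ridge very
  slowly; the scale move and the collapsed draws are what bring split-R̂
  below 1.01 at desk-scale chain lengths.

Two kernel details matter for robustness:

* **Empty-class updates are skipped.** If a sweep assigns nobody to a class,
  redrawing that class's intercepts from their N(0, 1) prior would park them
  far from the response scale (Likert means ≈ 3.5) and make the empty class
  absorbing. Skipping the update is an equally valid Gibbs kernel and keeps
  the class parameters data-anchored so the class can repopulate. When class 2
  is occupied in fewer than 1% of kept sweeps (reported as
  `LcCfaResults.class2_occupancy`), its parameters are deliberately
  unexplored and are excluded from the convergence gate.
* **Initialization targets the intended mode.** The mixture posterior can
  hold two rival modes: the intended one (class 2 = random responders) and a
  spurious one in which class 2 collects merely *noisy humans* — thresholded
  Likert data are not exactly normal, so an intercept-only class fits weak
  responders tolerably when communalities are low. Chains start with class-1
  parameters at the preliminary ML-CFA solution and class-2 parameters at the
  uniform-responding values implied by the code range (mean = midpoint,
  variance = (K²−1)/12). The class-model slope on the variability index
  starts at −3 per SD **only if** some respondents' raw ϒ2 actually
  approaches the uniform-responding value (above the midpoint between the
  sample median and (K²−1)/12, in at least 2% of rows); otherwise it starts
  at zero and the chains begin with everyone attentive. On contaminated data
  this seeds class 2 with the genuinely random rows; on clean data it
  prevents the spurious mode from capturing high-variability humans.

For binary/count items the measurement blocks lose conjugacy; factor scores
are sampled explicitly and measurement parameters use vectorized
Metropolis-within-Gibbs with Robbins-Monro step-size adaptation during
burn-in. The class-2 intercepts are estimated freely by default (the
equal-probability case τ_j2 = 0 is nested); `ModelSpec.fix_class2_intercepts`
pins them at zero.

The one-class `BayesianCFA` baseline is the class-1 model with identical
priors and the same kernel minus the mixture blocks.

Classification: bot iff posterior bot probability > 0.5 (tie → human);
the threshold is exposed everywhere.

## Convergence diagnostics

`split_rhat` and `effective_sample_size` implement the rank-normalized
split-R̂ and bulk ESS (Vehtari et al. 2021: pooled fractional ranks with the
3/8 offset, normal scores, halved chains; Geyer initial-monotone
autocorrelation sums for ESS). They are tested to 1e-6 agreement against the
independently maintained implementation in `arviz`. A fit is flagged
`converged` only if every monitored parameter (intercepts, free loadings,
Φ entries, residual variances, β) has split-R̂ < 1.01. Per-person quantities
are derived, not monitored. An ESS below 400 triggers a warning in the CLI.

## Synthetic data

`SimulationDesign`/`generate_dataset` emulate the reference study conditions:

* humans: latent responses Y* = Λη + ε standardized to unit variance, with
  per-item communalities uniform in (mean ± 0.15), mean itself uniform in
  [0.25, 0.64] per replication; equicorrelated factors with ρ ~ U(0, 0.7);
  Y* cut at thresholds (−2, −1, 0, 1, 2) into six categories coded 1–6;
* bots: every cell i.i.d. uniform on {1, …, 6}; exactly round(prop_bots·N)
  rows, shuffled among the humans;
* defaults: N = 400, 3 factors × 6 items, 25% bots.

Communality draws are clipped to [0.05, 0.95] so residual variances stay
positive (no clipping occurs under the default ranges). What the generator
does **not** emulate: missing data, non-random careless styles
(straight-lining, mimicry), model misspecification for the attentive class,
unequal items per factor in the grid runner. Passing tests therefore say
nothing about those regimes.

### The observed-metric population values

Cutting a standard-normal response into six categories at the thresholds
above multiplies every inter-item correlation by a constant factor
a₁²/Var(Y) with a₁ = 2φ(2) + 2φ(1) + φ(0) ≈ 0.991 and Var(Y) ≈ 1.067 —
i.e. standardized loadings shrink by a factor ≈ 0.9595 for *any* estimator
of the categorized responses, even with zero contamination. This attenuation
is a property of the response format, not of the model under study, so
percent bias of loadings and factor variances is scored against the
observed-metric population values `TrueParameters.loadings_std_observed`
(= 0.9595 × the latent loadings); factor correlations are invariant to the
attenuation and are scored against the drawn ρ. Replications whose drawn
|ρ| < 0.05 are excluded from correlation-bias aggregation (percent bias is
unstable near zero truth).

## Study runner and problem sizes

`run_study` generates, fits (mixture and baseline), and scores each
replication; aggregates are over converged replications only, and every
per-replication record is retained and written incrementally. A failed
replication is recorded as nonconverged, never aborts the study. All seeds
derive deterministically from one master seed.

Desk-scale defaults: 20 replications per condition with 3 chains × 4,000
iterations (2,000 burn-in) for the mixture. The one-class baseline has a far
simpler posterior (its split-R̂ is well below 1.01 already at short chains),
so the runner accepts separate, shorter settings for it; the acceptance
script uses 3 × 2,000 (1,000 burn-in). The full reference design (18
conditions × 500 replications × 12,000 iterations) is available via
`botclass study --full-scale`. The known breakdown regime (N = 200, six
factors, 50% bots) produces bimodal variance estimates; an optional
post-hoc outlier filter (`aggregate(variance_bias_cutoff=200)`) mirrors the
reference study's inspection and is off by default.

## Numerical choices and edge cases

* Sample variances in ϒ2 use the unbiased (n−1) denominator; the choice is a
  constant factor absorbed by standardization.
* The preliminary ML CFA treats Likert codes as continuous, uses L-BFGS on
  the profile of the Gaussian likelihood (saturated means), starting values
  (unit loadings, Φ = I, σ² = half the sample variances), tolerance 1e-6,
  max 500 iterations; on non-convergence it returns the starting values with
  a warning (ϒ1 stays computable). A near-singular sample covariance gets a
  ridge of 1e-8 · mean diagonal.
* Degenerate design intervals return their constant; a zero-variance index is
  left unscaled with a warning; a zero-variance chain returns R̂ = 1 by
  convention.
* Likert codes are used as-is (0- or 1-based both work): every downstream
  quantity is location/scale-equivariant or standardized.

## Known limitations

* Sensitivity to model misspecification of the attentive class is untested.
* Bots with non-uniform (human-mimicking) strategies are outside the model's
  assumptions.
* The binary/count samplers are Metropolis-based and mix more slowly than the
  continuous kernel; they are provided for completeness and smoke-tested, not
  tuned to the same convergence guarantees.
* At N ≈ 200 with many factors and 50% bots the mixture is known to break
  down occasionally (bimodal estimates); inspect per-replication records.
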