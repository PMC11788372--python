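# Methods

## The joint model

`tmbjoint` fits paired immunotherapy endpoints — a binary tumor-response
indicator and a right-censored time-to-event (TTE) outcome such as
progression-free survival — as one model linked by a patient-level shared
random effect:

* response: `logit P(Y_i = 1 | Z_i, TMB_i, b_i) = alpha_z' Z_i + alpha_m TMB_i + b_i`
* hazard: `h_i(t) = lam t^(lam-1) exp(beta_z' Z_i + beta_m TMB_i + b_i)`
* `b_i ~ N(0, sigma_b^2)`, independent across patients.

There is no intercept in either linear predictor; covariates are `Z` (the
simulators use a single `Z ~ U(0,1)`), and TMB (tumor mutation burden,
mutations/Mb) is the biomarker of interest. The baseline hazard is the
unit-scale Weibull `h0(t) = lam t^(lam-1)` with cumulative baseline `t^lam`;
any scale constant is absorbed by the covariate part, so `lam = 1` is the
constant-hazard (exponential) case. The marginal likelihood integrates `b_i`
out with Gauss–Hermite quadrature (order 21 by default); quadrature is used
only for likelihood evaluation and the corrected-score estimating equation —
the MCMC samplers augment `b_i` instead.

Priors (the "non-informative" defaults): `N(0, 10^2)` on each regression
coefficient, `gamma(0.001, 0.001)` on the Weibull shape `lam`, and
`gamma(0.001, 0.001)` on the random-effect precision `sigma_b^-2`. The shape
parameter's gamma prior is placed on the shape itself (an ambiguity we had
to resolve; the rate alternative is nearly equivalent at these
hyperparameters). `lam` and the precision are sampled on the log scale with
the Jacobian included.

## Error channels

**TMB measurement error.** Observed TMB is `TMB* = TMB + e` with `TMB` and
`e` latent and independent. Two corrections are provided:

* **Corrected score (CSM)** for `e ~ N(0, sigma_e^2)` with *known*
  `sigma_e`. The estimating function is the complex-variable corrected
  score: for the per-patient marginal score `s_i(theta; tmb)`,
  `E_V Re s_i(theta; TMB* + i sigma_e V)` with `V ~ N(0,1)` is
  conditionally unbiased for `s_i(theta; TMB)` (the moment generating
  functions of the real error and the imaginary perturbation cancel). The
  score is computed analytically on the quadrature grid with
  softmax-normalized complex weights, so the doubly-exponential Weibull
  factor cancels between numerator and denominator. The V-integral is
  itself evaluated by Gauss–Hermite quadrature (8 nodes by default); the
  correction identity holds under any quadrature of that integral, so this
  is a deterministic, lower-variance drop-in for the classical seeded
  Monte-Carlo variant, which remains available (`v_method="mc"`). A
  large-sample check (n = 20,000) shows the mean corrected score at the
  generating parameters below 0.007 per patient in every component, versus
  a beta_m component of +0.25 for the naive score. Corrected-score
  objectives are unbounded far from the origin (the exp-moment correction
  vanishes as |beta_m| grows), so the solver targets the consistent root:
  Levenberg–Marquardt started at the naive MLE, with a basin guard and up
  to two jittered retries. Uncertainty is the sandwich `A^-1 B A^-T` from
  numerically differenced per-patient scores; near-zero curvature
  directions (e.g. `sigma_b -> 0`) are eigenvalue-floored at 1% of the
  largest curvature so the sandwich cannot explode numerically.

* **Bayesian error correction (ECM)** when the error law is unknown. Both
  the error density `f_e` and the true-TMB density `f_TMB` get truncated
  Dirichlet-process mixture-of-normals priors (stick-breaking, truncation
  20, concentration 1.0, normal-inverse-gamma base with `k0 = 0.1`,
  `a0 = 2`, `b0 = 1`; base mean 0 for `f_e` and the sample mean of observed
  TMB for `f_TMB`). The number of occupied components is data-determined.
  Per-patient true TMB is a latent variable updated by random-walk
  Metropolis against the outcome likelihood and both mixture densities.
  Location identifiability: `TMB* = TMB + e` is invariant to shifting mass
  between the two densities, so after each sweep the error mixture is
  recentred to mean zero, with the shift absorbed into the TMB mixture and
  the latent TMB values. This is a deterministic move along the weakly
  identified direction rather than an exact MCMC move; the retained-draw
  summaries of `err_mix_mean` confirm it holds the constraint to machine
  precision.

**Response misclassification (MCM).** Observed response `R` relates to the
true state `Y` through sensitivity `eta = P(R=1|Y=1)` and specificity
`delta = P(R=0|Y=0)`: `P(R=1) = eta P(Y=1) + (1-delta)(1-P(Y=1))`. Without
constraints `(eta, delta)` are not practically identifiable, so informative
Beta priors are required; defaults are `eta ~ Beta(9, 1)` and
`delta ~ Beta(72.5, 2.5)`. Note that Beta(72.5, 2.5) has mean 72.5/75 =
0.9667 — the frequently quoted 0.98 is its *mode* (71.5/73); all summaries
in this package use exact Beta arithmetic. The sampler augments `Y_i` from
its exact Bernoulli full conditional and updates `eta`, `delta` from
conjugate Beta full conditionals, rejecting draws with `eta < 1 - delta`
(the label-flip region). With subgroup labels, per-subgroup `eta_g`,
`delta_g` can be sampled on the logit scale under a shared normal
hyperprior (`hierarchical=True`).

**Pairwise control (PECM)** runs both channels simultaneously: latent TMB,
latent responses, both mixtures and `(eta, delta)` in one Gibbs sweep.

## The sampler

One Metropolis-within-Gibbs kernel serves all four variants:

1. (ECM) conjugate sweeps of both DP mixtures; recentring; vectorized
   random-walk update of latent TMB.
2. (MCM) exact latent-response draw; conjugate (or logit-RW) `eta`/`delta`.
3. Vectorized per-patient random-walk update of `b` (target acceptance
   0.44).
4. Joint random-walk blocks for the response and hazard coefficients and a
   scalar update of `log lam` (target 0.3).
5. Conjugate gamma draw of the precision `sigma_b^-2`.
6. A joint scale move multiplying all `b_i` and `sigma_b` by a common
   factor (with the exact Jacobian), which breaks the slow mixing of the
   centered random-effect parametrization; without it `sigma_b` has an
   effective sample size an order of magnitude lower.

Proposal scales adapt by Robbins–Monro *during burn-in only*, so retained
draws come from a fixed kernel. A seed is mandatory; chains are spawned
from a `SeedSequence`, and identical seeds give bit-identical draws. The
point estimator is the mean of the retained draws; summaries also report
the posterior SD, equal-tailed 95% credible interval, bulk ESS and split
R-hat (via arviz). Engine correctness is cross-checked in the test suite
against an independent affine-invariant ensemble sampler (emcee) targeting
the same analytically marginalized posterior (Kolmogorov–Smirnov distance
on `beta_m` draws < 0.08).

### A caution on the misclassification posterior

Under the default priors the MCM/PECM posterior for `alpha_m` is genuinely
heavy-tailed to the right: there is a ridge in which `eta` drifts low,
latent labels flip toward the model's own predictions and `alpha_m`
inflates (posterior separation). This is a property of the model and
priors, not of the sampler — the emcee cross-check on the marginalized
posterior reproduces the same tail mass to three decimals. Consequently the
posterior-mean point estimate depends on how much of that ridge a finite
chain visits. Under the standard weak-signal misclassification scenario
(n = 200, `alpha_m = 0.4`), the median per-replicate posterior mean at the
harness chain budget is about 0.43, but a substantial minority of chains
visit the ridge and return `alpha_m` of 2–5, inflating across-replicate
averages; long chains (50,000+ iterations) visit it proportionally to its
true posterior mass. R-hat flags the affected fits. With stronger signal
(the threshold-demonstration preset, n = 500) the posterior is
well-identified and the ridge is negligible. For substantive analyses we
recommend multiple chains, attention to R-hat on the response
coefficients, stronger priors on `eta` where defensible, and reporting
posterior medians alongside means; the heavy tail itself is diagnostic of
weak identification.

## Synthetic cohorts

The generator draws, per patient: `Z ~ U(0,1)`; true TMB from a named law
(default `Laplace(mean 1, SD 1.5)`; distribution specs always take mean and
SD, so a variance printed as `1.5^2` is `sd=1.5`); `b ~ N(0, 0.5^2)`;
`Y ~ Bernoulli(expit(alpha'x + b))`; event time by inverse-CDF from the
model's own cumulative hazard with Weibull shape 1.0; censoring
`C ~ U(0, 10)` (roughly 30% censoring at the default coefficients);
additive TMB error (normal, or a Gumbel standardized to mean 0/SD 1 —
"extreme value" — whose skewness 1.14 distinguishes it from the normal);
and misclassified `R` from `(eta, delta)`. Default coefficients are
`alpha_z = -0.8`, `alpha_m = 0.4`, `beta_z = 1.0`, `beta_m = -0.4`,
`lam = 1.0`, `sigma_b = 0.5` at `n = 200`; the threshold-demonstration
preset uses `n = 500` with `alpha_z = -1.8`, `beta_z = 2.2`. What the
generator does *not* emulate: covariate correlation structures, informative
censoring, non-additive or TMB-dependent measurement error, and panel- or
assay-specific TMB discreteness. Passing tests therefore demonstrate
correctness of the estimators under the stated generative assumptions, not
robustness to every feature of real assay data.

## Threshold localization

Candidate cutoffs are midpoints between consecutive sorted unique TMB
values whose split keeps at least `min_frac` (default 10%) of patients on
each side — an unconstrained minimum-p scan selects degenerate cutoffs.
Each candidate is scored by the two-sample log-rank test (native risk-set
implementation, validated against lifelines), Fisher's exact test on the
2x2 response table, and Fisher's combination `-2(log p_lr + log p_resp) ~
chi^2_4`; the scan is exhaustive and ties break toward the smaller cutoff.
`logrank_only` and `response_only` modes are available. Which columns are
scanned encodes the error correction: observed TMB/response for naive and
corrected-score fits, posterior-mean TMB for ECM/PECM, posterior
`P(Y=1)` dichotomized at 0.5 for MCM/PECM. No multiple-testing adjustment
is applied to the scan by design; the scan table is returned in full so
users can apply their own.

## Study harness

`run_estimator_study` repeats generate-and-fit over seeded replicates and
reports, per parameter: the mean point estimate ("fitted"), bias (fitted
minus truth), "SE" — defined here as the mean over replicates of the
per-fit uncertainty (posterior SD for Bayesian fits, sandwich SE for the
corrected score) — and "SD", the empirical SD of the point estimates
across replicates. Replicate seeds are spawned hierarchically, so growing
the replicate count preserves earlier replicates. Harness defaults chosen
for the bundled studies: 100 replicates, single chain of 3,000 iterations
with 1,500 burn-in per fit; a full-fidelity run (500 replicates, longer
chains) is a command-line flag away but takes correspondingly longer.
`roc_compare` scores observed, posterior-mean and true TMB against true
response labels with the Mann–Whitney rank AUC (the fitted logistic
predictor is monotone in TMB, so column AUC equals predictor AUC).
`perturb_labels` implements artificial response-label perturbation (e.g.
25% of responders, 2% of non-responders) for robustness experiments on
user-supplied cohorts.

## Numerical choices and edge cases

* Gauss–Hermite order 21 for all random-effect integrals; order 8 for the
  corrected-score V-integral (the root moves by < 0.002 between orders 8
  and 24).
* ECM/PECM mixture parameters are re-swept on alternate iterations (a
  valid fixed-scan Gibbs schedule); the latent TMB and all core blocks
  update every iteration.
* Logistic log-likelihoods use `log(sigmoid)` forms with real-part clipping
  at ±60 (complex path) to avoid overflow; the Weibull exponent is capped
  at 500 before exponentiation.
* Degenerate inputs: cohorts with all-equal TMB are rejected by the
  threshold scan and flagged (mixture collapse) by ECM; `t <= 0` and
  non-binary responses are rejected at cohort validation with the
  offending row named.
* The `eta/delta` conjugate update retries up to 100 times to satisfy
  `eta > 1 - delta`, keeping the previous values if the constraint cannot
  be met.
* All stochastic entry points require explicit seeds; there are no hidden
  global RNG dependencies.

## Known limitations

* Deconvolution of the TMB distribution converges slowly: at `n = 200` the
  ECM response-side coefficients retain visible finite-sample
  overcorrection (posterior means move markedly closer to truth by
  `n = 2000`).
* The minimum-p combined statistic is a pragmatic choice; the scan is
  agnostic to it, and other combination rules can be plugged in.
* No competing risks, time-varying covariates, or non-Weibull baselines;
  no misclassification model for the TTE endpoint (continuous-endpoint
  errors have little effect on consistency here).
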