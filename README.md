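# tmbjoint

Joint Bayesian modelling of paired immunotherapy endpoints — binary tumor
response and right-censored progression-free survival — with explicit
control of the two measurement-error channels that bias biomarker studies:
additive error in tumor mutation burden (TMB) and misclassification of the
response label. Fitted models drive a minimum-p scan that localizes the
TMB-positive stratification threshold.

## Who it is for

Biostatisticians and computational oncologists who need TMB cut-points (or
any error-prone continuous biomarker threshold) from cohorts where neither
the biomarker nor the response label can be trusted at face value. The
package ships a seeded cohort simulator, five estimators, a threshold
finder, a replicated-study harness and a small CLI.

## The model

For patient *i* with covariates `Z_i`, biomarker `TMB_i` and shared random
effect `b_i ~ N(0, sigma_b^2)`:

    logit P(Y_i = 1) = alpha_z' Z_i + alpha_m TMB_i + b_i          (response)
    h_i(t) = lam t^(lam-1) exp(beta_z' Z_i + beta_m TMB_i + b_i)   (hazard)

Observed data may carry `TMB*_i = TMB_i + e_i` and a misclassified response
`R_i` with sensitivity `eta = P(R=1|Y=1)` and specificity
`delta = P(R=0|Y=0)`. Estimators:

| name | error handled | approach |
|------|---------------|----------|
| `fit_bayes_nm` | none | MCMC on the joint model |
| `corrected_score_estimate` | TMB error, known normal `sigma_e` | complex-variable corrected score, sandwich SEs |
| `fit_bayes_ecm` | TMB error, unknown law | Dirichlet-process mixture deconvolution, latent true TMB |
| `fit_bayes_mcm` | response misclassification | latent true response, Beta priors on `(eta, delta)` |
| `fit_bayes_pecm` | both | joint augmentation |

Ignoring the errors attenuates the biomarker coefficients (naive `beta_m`
shrinks from −0.4 to about −0.27 under unit normal TMB error; naive
`alpha_m` from 0.4 to about 0.23 under `(eta, delta) = (0.75, 0.98)`); the
corrected fits recover them. See `docs/methods.md` for the full model,
priors, sampler and caveats — including a genuine heavy right tail of the
misclassification posterior under weak signal.

## Worked example

Simulate a 500-patient cohort with both error channels active
(`alpha_z = -1.8`, `alpha_m = 0.4`, `beta_z = 2.2`, `beta_m = -0.4`,
`e ~ N(0,1)`, `(eta, delta) = (0.75, 0.98)`), fit the pairwise correction,
and compare thresholds:

```python
import tmbjoint as tj

sim = tj.generate_cohort(tj.get_preset("threshold_demo", seed=3))
fit = tj.fit_bayes_pecm(sim.observed, config=tj.MCMCConfig(seed=2))
print(fit.summary())
```

```
                mean      sd  ci_lower  ci_upper        ess    rhat
alpha_z      -2.0212  0.5649   -3.4315   -1.0821    28.3145  1.0671
alpha_m       0.6121  0.3787    0.1728    1.8049    37.1111  1.0413
beta_z        2.1589  0.2666    1.6992    2.7468    35.2489  1.0653
beta_m       -0.4810  0.0947   -0.6934   -0.3188    36.1324  1.0885
lam           0.9705  0.0765    0.8304    1.1374    31.7009  1.0699
sigma_b       0.5707  0.2080    0.0744    0.9591    19.8061  1.0926
eta           0.7710  0.0941    0.5842    0.9483    88.7501  1.0037
delta         0.9679  0.0200    0.9172    0.9948   471.5430  1.0028
```

Every coefficient sits within about one posterior SD of its generating
value, and the misclassification rates (truth 0.75 / 0.98) are recovered
from their priors plus data. Thresholds, using posterior TMB and the dichotomized
posterior response for the corrected fit versus raw columns for the naive
scan:

```python
scan = tj.scan_thresholds(sim.observed, tmb_values=fit.posterior_tmb,
                          response_values=(fit.posterior_y_prob > 0.5).astype(int),
                          tmb_source="posterior")
naive = tj.scan_thresholds(sim.observed)
comp = tj.compare_groups(sim.observed, scan.cutoff, tmb_values=fit.posterior_tmb,
                         response_values=(fit.posterior_y_prob > 0.5).astype(int))
```

```
PECM cutoff 0.969 (combined p 5.29e-28); naive cutoff 2.195 (combined p 1.76e-08)
groups 265/235, response rates 0.22 vs 0.45, log-rank p 6.13e-23, response p 1.27e-07
```

The corrected threshold (0.97) splits the cohort into groups whose response
rates (22% vs 45%) and survival curves separate far more sharply than the
naive scan's cutoff — the combined p improves by about twenty orders of
magnitude.

The same steps are available from a shell:

```bash
tmbjoint simulate --preset threshold_demo --seed 3 --out cohort.csv
tmbjoint threshold --cohort cohort.csv --variant pecm --seed 2 --out report.json
tmbjoint study --preset tmb_normal_error --estimators true_data,naive,csm \
               --n-reps 100 --seed 7 --out study.csv
```

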