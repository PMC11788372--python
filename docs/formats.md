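# File formats

All artifacts are plain delimited text or JSON.

## Cohort table (CSV/TSV)

One row per patient, snake_case header. Required columns:

| column | type | meaning |
|--------|------|---------|
| `response` | 0/1 | observed tumor response indicator `R` |
| `time` | float > 0 | observed follow-up time `T = min(U, C)` |
| `event` | 0/1 | event indicator (1 = event, 0 = censored) |
| `tmb_obs` | float | observed TMB (`TMB*`), mutations/Mb or simulated scale |

Optional columns: covariates `z1..zp` (constant dimension), `subgroup`
(categorical; absent means a single stratum). Extra columns are preserved
on read/write. Validation errors name the offending row and column.

Error-corrected fits append posterior columns via
`BayesResults.augmented_cohort()`: `tmb_posterior` (posterior-mean latent
TMB), `y_prob_posterior` (posterior P(true response = 1)),
`response_prob_posterior` (posterior mean model response probability).

## Truth sidecar (CSV)

Written next to simulated cohorts: `y_true`, `b`, `tmb_true`, `u` (event
time), `c` (censoring time), row-aligned with the observed table.

## Fit outputs

* `<out>.csv` — parameter summary (mean, sd, ci_lower, ci_upper, ess, rhat;
  corrected-score fits: estimate, se).
* `<out>_draws.csv` — retained MCMC draws, one column per parameter
  (chains concatenated), for external diagnostic tooling.

## Threshold report

* JSON: `cutoff`, `tmb_source` (observed | posterior | true), `combined_p`,
  and the full `scan` array of records `{cutoff, n_low, n_high, logrank_p,
  response_p, combined_p}`.
* The same scan table as CSV beside it.

## Study table (CSV)

Long format, one row per (estimator, parameter): `estimator`, `param`,
`fitted`, `bias`, `se`, `sd`, `n_reps`.

## Run manifest (JSON)

Written by every CLI subcommand: tool name and version, subcommand, seed,
the full argument set and elapsed seconds — sufficient to reproduce the
run exactly.
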