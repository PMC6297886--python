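# orddcm

Diagnostic classification models (DCMs) for **ordinal** item responses.

The package implements three confirmatory latent class models for
respondent-by-item matrices of ordered codes `0..M-1`:

- **NRDM** — nominal response diagnostic model: each response option of each
  item carries its own intercept and attribute-effect parameters;
- **ORDM** — ordinal response diagnostic model: the NRDM constrained so each
  item has a single effect vector entering cumulatively across ordered options
  (adjacent-category form), with monotone option intercepts and positive
  effects;
- **MORDM** — modified ORDM: option intercepts further decomposed into an
  item-general intercept plus option intercepts shared by all items measuring
  the same attribute set (via the W-matrix).

Ordering and sign constraints are enforced through a *pseudo*
parameterization (option-1 base plus sign-constrained increments), so every
parameter vector visited during estimation is valid by construction.

## Features

- **design** — profile enumeration, Q-matrix / W-matrix handling, effect-term
  expansion up to arbitrary interaction order, structural parameter counting.
- **models** — probability kernels for all three models, pseudo/natural
  transforms, constraint validation, latent-class marginal likelihood.
- **simulate** — seeded synthetic respondents from any model (profile draws
  and response draws on independent sub-streams).
- **estimate** — Bayesian MCMC (Metropolis-within-Gibbs on the augmented
  model with adaptive scalar and block proposals; truncated N(0, 20) priors on
  item parameters, Dirichlet(2) on prevalence; default 2 chains x 6,000
  iterations with 2,000 burn-in), a deterministic MAP/EM fallback with the
  same likelihood/constraints/priors, split-chain R-hat (threshold 1.1),
  Brooks-Gelman multivariate R-hat, and PSIS-LOO fit indices (ELPD / LOOIC).
- **score** — posterior profile probabilities, MAP profiles, marginal
  (continuous) attribute scores, binary calls, crosstabs, Cohen's kappa,
  RMSD, response-option curve tables.
- **study** — parameter-recovery harness: simulate / fit / classify over R
  replicates with bias, (R-1)-divisor RMSE, and classification-accuracy
  descriptives.

## CLI

All commands live under a single entry point:

```bash
orddcm count-params --model ordm --q q.csv --options 4
orddcm simulate --model ordm --params params.json \
    --prevalence 0.351,0.074,0.156,0.419 --q q.csv -n 500 --seed 1 --out data/
orddcm fit --model ordm --data data/responses.csv --q q.csv \
    --chains 2 --iter 6000 --burnin 2000 --seed 1 --out fit/
orddcm classify --data data/responses.csv --params fit/params.json \
    --prevalence 0.351,0.074,0.156,0.419 --q q.csv --out scores.csv
orddcm compare --a scores_a.csv --b scores_b.csv --out cmp
orddcm roc --params fit/params.json --q q.csv --item 1 --out roc.csv
orddcm loo --pointwise fit/pointwise_loglik.csv
orddcm recovery-study --config study.json
```

Formats are plain text throughout: CSV for responses (header = item ids),
Q-matrices (first column = item ids, header = attribute ids), crosstabs and
curves; JSON for parameters, configurations and reports.

## Python API sketch

```python
import orddcm as od
from orddcm import reference

q = reference.survey_q_matrix()            # 8 items, 2 attributes
params = reference.ordm_generating_params()
pi = reference.generating_prevalence()

data = od.generate_dataset("ordm", params, pi, n=500, seed=1, q=q)
summary = od.fit("ordm", data, q, od.SamplerConfig(seed=1))   # MCMC
result = od.classify(data.responses, summary.params, summary.prevalence, q)
```

`orddcm.reference` ships the built-in example design (8 four-option items,
two attributes) and published generating parameter sets used as recovery-study
defaults.

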