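# botclass

Bayesian latent-class confirmatory factor analysis for **automated bot
detection in online survey data**.

Online panels (MTurk and its relatives) are contaminated by bots and
click-farm workers whose answers are independent of item content. Such rows
act as random noise: they pull inter-item correlations toward zero, so factor
loadings, factor variances and factor correlations estimated by an ordinary
CFA are severely attenuated. `botclass` is for researchers analyzing
questionnaire data who want to *detect the bots and estimate the measurement
model at the same time*, instead of filtering on ad-hoc cutoffs and hoping.

## The model

A two-class mixture. Class 1 (attentive respondents) follows a
simple-structure factor model; class 2 (bots) is intercept-only:

    g(μ_y,ij | C_i = 1) = τ_j1 + λ_j η_i,     η_i ~ MVN(0, Φ)
    g(μ_y,ij | C_i = 2) = τ_j2
    y_ij | C_i = c  ~  F(μ_y,ij, σ²_jc)

with identity/normal, logit/Bernoulli or log/Poisson response families.
Class membership is predicted from two person-level indices through a
logistic model,

    P(C_i = 1 | ϒ1_i, ϒ2_i) = expit(β0 + β1·ϒ1_i + β2·ϒ2_i),

where ϒ1 is a likelihood-based person-fit index (log-likelihood deficit
relative to the saturated sample moments, from a preliminary ML CFA) and ϒ2
is a nonparametric **variability index** — the within-factor response
variance averaged over factors, which is small for content-driven answers
and large (≈ 35/12 on a 6-point scale) for uniform random ones. Estimation
is by MCMC with weakly informative priors; per-person posterior bot
probabilities come out of the mixture by Bayes' rule. Because class 2 has no
loadings, the classes cannot label-switch. A one-class `BayesianCFA`
baseline (what a researcher unaware of bots would fit) is included for
comparison. See `docs/methods.md` for priors, the sampler, and diagnostics.

## Worked example

```python
from botclass import (SimulationDesign, generate_dataset, LatentClassCFA,
                      sensitivity_specificity, percent_bias)

design = SimulationDesign(n_persons=400, n_factors=3, prop_bots=0.25, seed=2024)
data, truth = generate_dataset(design)

model = LatentClassCFA(data)           # indices computed automatically
result = model.fit(chains=3, iterations=4000, burnin=2000, seed=1)

pred = result.classify(threshold=0.5)
print(sensitivity_specificity(truth.class_labels, pred))
print(result.summary().loc[["beta[0]", "beta[1]", "beta[2]"]].round(2))
print(percent_bias(result.standardized_loadings_mean, truth.loadings_std_observed))
```

prints

```
converged: True  max split-Rhat: 1.009
sensitivity 1.000  specificity 0.987
         mean    sd   2.5%  97.5%  rhat      ess
beta[0]  1.24  0.74  -0.22   2.74  1.01   834.05
beta[1]  0.05  0.80  -1.53   1.63  1.00  1332.66
beta[2] -9.74  1.69 -13.39  -6.87  1.00  1333.14
standardized-loading percent bias: +1.3%
```

All 100 planted bots are flagged and 99% of humans retained. The credible
interval of β2 (the variability index) excludes zero — high within-factor
variability predicts bot membership — while the person-fit index ϒ1 adds
little (its interval covers zero), and the class-1 standardized loadings are
essentially unbiased. Fitting the same data with `BayesianCFA` instead gives
loadings biased by roughly −27%.

## Command line

```bash
botclass simulate --n 400 --factors 3 --prop-bots 0.25 --seed 7 --out sim.csv
botclass indices  --data survey.csv --map config.yaml --out indices.csv
botclass fit      --data survey.csv --map config.yaml --out results/
botclass detect   --config config.yaml        # end-to-end workflow
botclass study    --reps 20 --out study_out/  # Monte-Carlo study grid
```

`config.yaml` maps items to factors and lists reverse-coded items (recoded as
min+max−y before analysis, as required by the positive-loading priors):

```yaml
data: survey.csv
factors:
  SDO: [SDO1, SDO2, SDO3, SDO4, SDO5, SDO6, SDO7, SDO8]
  RWA: [RWA1, RWA2, RWA3, RWA4, RWA5]
reverse_coded: [SDO3, SDO4, SDO7, SDO8]
chains: 3
iterations: 12000
burnin: 6000
seed: 1
```

Exit codes: 0 ok, 1 input error, 2 the convergence criterion
(split-R̂ < 1.01 on every monitored parameter) was not met.

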