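# contactweave

Analysis pipeline for **diary-based social contact surveys** — the kind of
community survey used to measure who mixes with whom, so that age-structured
transmission models of respiratory pathogens (influenza, SARS-CoV-2, pertussis,
…) can be parameterised with empirical contact rates. It was built around a
quota-sampled urban/rural survey design from Cambodia, but the machinery is
generic for any two-table (participants + contacts) survey in the POLYMOD
tradition.

The package takes you from raw delimited tables to:

* validated, canonicalised survey data (participants, diary contacts, and
  coarse-band *supplementary* contact counts for contacts recalled but not
  diarised),
* per-participant **raking** (iterative proportional fitting) weights matched
  to population margins (urban/rural, age group, weekday/weekend, employment
  status),
* weighted, **reciprocity-corrected age mixing matrices**, stratified by
  setting (home with/without household members, work, school,
  other/transport/leisure) and by urban/rural residence,
* descriptive summaries (degrees, contact hours, setting proportions,
  intensity trends, distance and mobility tables, diary-vs-supplementary
  reporting comparisons), and
* multivariable **negative-binomial regression** of contact degree and total
  contact hours.

A synthetic-survey generator with exactly known ground truth makes the whole
pipeline verifiable end to end without access to any field data.

## The core statistics

**Mixing matrix.** For age bands *i*, *j* (5-year bands to 64, then 65+),
the raw matrix entry is the weighted mean number of diary contacts per day a
band-*i* participant reports with band-*j* contactees:

```
c_ij = Σ_{p ∈ band i} w_p n_pj / Σ_{p ∈ band i} w_p
```

Because contacts are mutual, band-level totals must balance:
`c_ij N_i = c_ji N_j`, with `N_i` the population of band *i*. Sampling and
reporting error break this in raw data, so matrices are symmetrised by

```
c'_ij = (c_ij N_i + c_ji N_j) / (2 N_i)
```

which enforces the balance exactly and conserves the total number of contact
events. Supplementary contacts never enter matrices (their settings and exact
ages are unknown).

**Raking.** Weights `w_p` are fitted by iterative proportional fitting so
that weighted sample margins match supplied population shares on several
variables simultaneously, with optional trimming to bound design effects.

**Degree models.** Contact degree (diary + supplementary) and total contact
hours (duration-band midpoints, right-truncated at 4 h) are modelled by
NB2 negative-binomial regression with a log link,
`log μ_p = x_p'β`, `Var(y) = μ + α μ²`, fitted by joint maximum likelihood
with the raking weights entering the likelihood; exponentiated coefficients
are relative rates against reference levels, with per-term likelihood-ratio
ANOVA.

## Worked example

```python
import numpy as np
from contactweave import (GeneratorConfig, MarginSpec, generate_survey,
    rake_weights, mean_contact_matrix, reciprocity_adjust,
    participant_summaries, weighted_median_iqr, fit_nb_model)

survey, truth = generate_survey(GeneratorConfig(n_participants=2016, seed=1))

specs = [MarginSpec(v, t) for v, t in truth.weights_target_margins.items()]
w = rake_weights(survey, specs)

summ = participant_summaries(survey)
med, q1, q3 = weighted_median_iqr(summ["degree_total"], w.weights)
print(f"weighted median degree: {med:.0f} (IQR {q1:.0f}-{q3:.0f})")

pop = truth.population["all"]
adj = reciprocity_adjust(mean_contact_matrix(survey, w, population=pop), pop)
resid = adj.values * pop.N[:, None] - (adj.values * pop.N[:, None]).T
print(f"reciprocity residual after adjustment: {np.nanmax(np.abs(resid)):.2e}")

fit = fit_nb_model(survey, w, covariates=("residence", "day_type", "age_band"))
print(fit.summary())
```

prints

```
weighted median degree: 21 (IQR 9-44)
reciprocity residual after adjustment: 5.82e-11
Negative binomial regression — response: degree_total
n = 2016, dispersion alpha = 0.8685, log-likelihood = -8937.72

variable        level                 rate              95% CI
intercept                            19.85       (17.61-22.38)
residence       rural                 1.26         (1.16-1.36)
day_type        weekend               0.90         (0.80-1.01)
age_band        15-24                 1.54         (1.33-1.79)
...
residence       urban                 1.00                 REF
```

The median participant reports 21 contacts per diary day under the default
generator conditions; the adjusted matrix balances contact totals to
floating-point precision; and the regression recovers the generating rural
relative rate (truth 1.23, estimate 1.26 with CI 1.16–1.36).

## Command line

```
contactweave simulate --out dir/ --seed 1          # synthetic CSV trio + population
contactweave validate participants.csv contacts.csv
contactweave run config.yaml --seed 1              # full pipeline, hashed manifest
```

`run` executes validate → weights → matrices → describe → regress from one
YAML config and writes a JSON manifest with a content hash per artifact, so a
fixed seed and config reproduce outputs bit for bit.

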