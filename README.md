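# netsurv

**Age-standardized net survival for population-based cancer cohorts.**

Cancer registries summarise patient survival as *net survival*: the
survival patients would experience if the cancer under study were the only
possible cause of death.  Because other-cause mortality and cancer
survival both vary strongly with age, registry comparisons rest on two
operations — removing expected (background) mortality using population
lifetables, and age-standardizing the result, either to the cohort's own
age mix (internal) or to the International Cancer Survival Standard (ICSS)
reference weights (external).

There has been debate over which estimator should perform the first step.
`netsurv` implements the competing approaches as one tested pipeline so
that they can be compared like for like:

* **Ederer II** — the traditional lifetable estimator: per monthly
  interval, excess deaths (observed − expected) over person-time,

  `λ_j = (Σ_i d_ij − Σ_i d*_ij) / Σ_i y_ij`,  `R_j = exp(−Σ k_j λ_j)`;

* **Pohar Perme** — the same construction with every subject weighted by
  the inverse of their expected survival, `w_ij = 1/S*_ij`, removing the
  informative depletion of high-background-mortality (older) subjects;
* **Brenner** — all-age Ederer II with subjects re-weighted (`w_k/a_k`)
  so the age mix at diagnosis matches a reference population;
* **flexible parametric modelling** — a spline model for the log
  cumulative excess hazard (5 df baseline, grouped or continuous age,
  3-df time-dependent effects), whose per-subject predicted curves are
  averaged into internally or externally standardized estimates;
* a **synthetic-cohort simulator** with two calibrated scenarios whose
  true net survival is known analytically (scenario 1: age effect decays
  over follow-up; scenario 2: it persists), and an **evaluation harness**
  reporting bias, MSE and coverage per estimator over replicate cohorts.

The package-level finding mirrors what the simulations show: once you
age-standardize, all the nonparametric routes are nearly unbiased even
under extreme age-variation in excess mortality, and the traditional
age-standardized Ederer II (and continuous-age modelling) buy better
long-term precision than Pohar Perme weighting.

## Worked example

Simulate one scenario-2 cohort (persistent age effect, n = 15,000),
estimate net survival four ways, and compare against the generator's
truth:

```python
import numpy as np
from netsurv import (EdererII, PoharPerme, FlexibleParametricModel,
                     ederer2, generate_cohort, gompertz_ratetable,
                     internal_weights, scenario_spec, split_monthly,
                     standardize_grouped, true_standardized)

rt = gompertz_ratetable()                  # popmort table: rate = exp(-10.2 + 0.095 age)
spec = scenario_spec(2)                    # calibrated scenario 2
rng = np.random.default_rng(np.random.SeedSequence((2024, 0)))
cohort = generate_cohort(spec, rt, rng)

times = np.array([5.0, 10.0, 15.0])
ages = cohort["age_diag"].to_numpy()
truth = true_standardized(spec, times, "internal", ages=ages)

pp = PoharPerme().fit(cohort, rate_table=rt)           # all-age, inverse weights
e2 = EdererII().fit(cohort, rate_table=rt)             # all-age, unweighted
it = split_monthly(cohort, rt)                         # grouped Ederer II, Eq-style
w = internal_weights(ages)
g = w.group_index(ages)
e2_std = standardize_grouped([ederer2(it.subset(g == k)) for k in range(5)], w)
fpm = FlexibleParametricModel(age="continuous").fit(cohort, rate_table=rt)
model = fpm.standardized_survival(ages, times, n_boot=0)

print("truth          ", np.round(truth * 100, 1))
print("Pohar Perme    ", np.round(pp.predict_relative_survival(times) * 100, 1))
print("Ederer II all  ", np.round(e2.predict_relative_survival(times) * 100, 1))
print("Ederer II std  ", np.round(e2_std.rel_surv_at(times) * 100, 1))
print("model (cont.)  ", np.round(model.rel_surv * 100, 1))
```

Output (internally age-standardized net survival, %):

```
truth           [62.8 52.6 46.2]
Pohar Perme     [64.  52.7 48.4]
Ederer II all   [64.5 54.2 48.7]
Ederer II std   [64.1 53.1 46.5]
model (cont.)   [63.9 53.1 46.9]
```

On a single replicate the estimates scatter around the truth (the
Pohar Perme estimate most widely at 15 years — its inverse-expected-
survival weights give a few very old survivors enormous influence), but
the systematic pattern only emerges over replicates: averaged over 200
cohorts the *all-age* Ederer II sits ≈ +2 pp above the truth at 15 years
because, with a persistent age effect, the subjects with the worst net
survival are also those preferentially removed by other-cause death —
exactly the bias that the weighting and standardization schemes largely
remove (`netsurv evaluate` reproduces the full bias/MSE/coverage table).

The same machinery is scriptable from the shell:

```sh
netsurv simulate --scenario 2 --n 15000 --seed 1 --out cohort.csv
netsurv estimate --cohort cohort.csv --method pohar_perme --out curve.csv
netsurv evaluate --scenario 2 --reps 200 --seed 1 --out report.csv
```

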