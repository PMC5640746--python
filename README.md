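# carenet

Structural analysis of mental-health service referral networks and their
association with patient outcomes.

Regional mental-health reforms often organize care as *networks* of
services — psychiatric wards, community mental-health teams, crisis and
outreach teams, primary care, social services, housing — that refer
patients to each other. `carenet` implements the full analysis chain for
studies that ask whether a network's **composition** (size, service-type
mix, index of dissimilarity), **integration** (density, Freeman degree
centralization, clustering, reciprocity) and **heterophily** (Coleman
homophily index per service type) are associated with patient-level
**continuity of care** (ACSS-MH, 31 items, total 31–155) and **social
integration** (SIX index, 0–6), in cohorts of patients clustered within
networks.

It is aimed at health-services researchers running (or re-analyzing)
inter-organizational survey studies: tie surveys are ordinal
(never/sometimes/often, over four relation kinds), networks are directed
and binary after dichotomization, and outcome models are multilevel.

## What it computes

**Network construction.** A directed edge *i→j* exists when at least one
clinical relation (referral sent by *i*, referral received reported by
*j*, or information exchange) reaches the dichotomization threshold
("sometimes or often" by default; "often only" as a sensitivity variant).
Networks are restricted to survey participants by default, or kept as
full matrices (non-respondents included via respondents' reports) as a
second sensitivity variant.

**Structural exposures.** For a network with `n` services and `E` edges:

- density `E / (n(n−1))`;
- Freeman in-degree centralization `Σᵢ(d_max − dᵢ) / (n−1)²` — 0 when all
  services have equal ties, 1 for an inward star;
- clustering: mean local density of ties among each service's neighbors
  (undirected projection);
- reciprocity: share of ties whose reverse tie exists;
- index of dissimilarity `½ Σₜ |pₜ − p̄ₜ|` against the study-average
  composition;
- Coleman homophily index per type: with `w` the within-type share of the
  type's out-ties and `e = (n_type−1)/(n−1)` its random-mixing
  expectation, `(w−e)/(1−e)` if `w ≥ e` else `(w−e)/e` — +1 all referrals
  within type, 0 random mixing, −1 none.

**Outcome models.** Continuity: linear mixed model (REML) with a network
random intercept, standardized betas, ICC `σ²ᵤ/(σ²ᵤ+σ²ₑ)`. Social
integration: random-intercept proportional-odds model fitted by maximum
likelihood with Gauss–Hermite quadrature, odds ratios, latent-scale ICC
`σ²ᵤ/(σ²ᵤ+π²/3)`. Model 1 enters each network metric separately (always
with age, sex, HoNOS and recruitment-service-type controls); Model 2 is
forward-stepwise selection among the Model-1-significant metrics.

**Synthetic studies.** Because tie surveys of this kind are rarely
deposited, `carenet.synthetic_data` generates full studies — typed random
digraphs with tunable density, homophily and hub centralization, plus
cluster-sampled patients whose outcomes carry planted network effects —
so the whole pipeline is testable end to end and estimator calibration
(type-I error, parameter recovery) can be demonstrated.

## Worked example

Simulate a 19-network study with a planted centralization effect on
continuity (0.10 standard deviations per SD of centralization), describe
the networks, and fit the Model-1 regression:

```python
from carenet import SimulationConfig, generate_study, build_network, metrics_table
from carenet.outcome_models import fit_continuity_bivariate, render_model_tables
from carenet.survey_io import analysis_set

cfg = SimulationConfig(seed=1, continuity_effects={"degree_centralization": 0.10})
study = generate_study(cfg)
by_net = {}
for s in study.roster:
    by_net.setdefault(s.network_id, []).append(s)
networks = [
    build_network(by_net[n], [t for t in study.ties if t.network_id == n])
    for n in sorted(by_net)
]
rows, summary = metrics_table(networks)
print(summary.loc[["n_services", "density", "degree_centralization", "clustering"]].round(3))

patients = analysis_set(study.patients)
result = fit_continuity_bivariate(patients, "degree_centralization", rows)
print(render_model_tables([result])[1])
```

prints

```
                         mean     std     min     max
n_services             28.421  12.672  11.000  49.000
density                 0.437   0.022   0.409   0.489
degree_centralization   0.416   0.055   0.300   0.496
clustering              0.687   0.030   0.637   0.749
== continuity (bivariate; std beta; n=1520, networks=19) ==
   [controlled for age, sex, HoNOS and recruitment service type]
  degree_centralization                 0.143   p=0.002
  age                                   0.005   p=0.016
  male                                 -0.089   p=0.075
  honos                                -0.022   p=0.000
  recruit_community_mental_health      -0.055   p=0.582
  ...
  ICC (network level)                   2.60%   p=0.000
  AIC                                    4247.8
```

The metric summary is the study's structural description (one row per
metric: mean, SD, min, max over the 19 analysis networks, as fractions).
In the model block, `0.143` is the standardized coefficient of
centralization on the continuity score — the planted 0.10 effect plus
sampling noise for one replicate — with its Wald p-value; the ICC row says
2.6% of outcome variance sits between networks; AIC is from the ML refit.

The same pipeline runs from the shell:

```bash
carenet run-study --seed 1 --out results/run1            # simulate + full analysis
carenet run-study --seed 1 --threshold often --out results/run2
carenet compare --a results/run1 --b results/run2 --out results/sensitivity.csv
```

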