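# Methods

This note documents the models and procedures implemented in `carenet`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Study design being modeled

The pipeline replicates the analysis structure of inter-organizational
referral-network studies in mental health: a set of regional service
networks (order 20), each surveyed with a one-mode roster instrument in
which every participating service rates its contact frequency with every
other network member (never / sometimes / often) for four relation kinds
(referrals sent, referrals received, patient-related information
exchange, organizational activities), plus a patient cohort
cluster-sampled inside each network (ten patients in each of eight
recruitment services spanning the care spectrum). Patient outcomes are
experienced continuity of care (ACSS-MH, 31 items rated 1–5, total
31–155) and objective social integration (SIX, four components summing
to 0–6); clinician-rated HoNOS (0–48), age and sex are covariates.

## Network construction

Ordinal ratings are dichotomized: a tie exists when the rating is
"sometimes" or "often" (main rule) or "often" only (sensitivity rule).
Only the three clinical relation kinds enter the analysis networks;
organizational ties are parsed and kept out. Direction conventions:

- `referral_sent` reported by *i* about *j* → edge *i→j*;
- `referral_received` reported by *j* about *i* → edge *i→j* (the mirror
  of a sent referral);
- `info_exchange` is kept directed reporter→alter; an option to
  symmetrize exists but is off by default, because the instrument is
  one-mode and each service rates its own contacts.

The kinds are merged by logical OR after thresholding. The survey
instrument does not define a reconciliation rule for dyads reported
under several kinds; OR treats "any clinical contact at threshold
frequency" as a tie, which matches the clinical-contact reading of the
network. Referral-only networks can be built by restricting
`relations_used`.

Scope: the main analysis keeps participating services only (their
reports are complete); the full-matrix sensitivity variant keeps
non-respondents as nodes, with incident edges necessarily one-sided
(only respondents' reports exist). Edges among participants are
identical across scopes by construction.

## Structural metrics

All metrics are stored as fractions; percentage scaling is a rendering
concern. For a directed network with `n` nodes and edge set `E`:

- **density** `|E| / (n(n−1))`, defined for `n ≥ 2`;
- **Freeman degree centralization** `Σᵢ (d_max − dᵢ) / (n−1)²` on
  in-degrees, defined for `n ≥ 3`. In-degree is the default because in a
  referral network ties received index a service's role as a
  destination/coordinator, and the two documented anchors (0 for equal
  degrees, 1 for a single service connected with all others, i.e. an
  inward star) are met by the `(n−1)²` normalization. Out-degree and
  total-degree variants are exposed;
- **clustering**: mean over all nodes of the local clustering
  coefficient on the undirected projection (edge *i–j* iff *i→j* or
  *j→i*); nodes with fewer than two neighbors contribute 0. The verbal
  definition of the measure ("density of connections around a service")
  is direction-free, hence the projection;
- **reciprocity**: share of directed edges whose reverse exists; defined
  when `|E| ≥ 1`;
- **composition**: fraction of nodes per service type over a fixed
  9-category taxonomy;
- **index of dissimilarity**: `½ Σₜ |pₜ − refₜ|`. The reference defaults
  to the unweighted mean composition across the study's networks (each
  network counting once, not each service); a pooled-services reference
  is available. The ID is the share of services that would need to
  change type to match the reference;
- **Coleman homophily index**, per service type: with `w` the share of
  the type's out-edges landing on same-type alters and
  `e = (n_type−1)/(n−1)` the random-mixing expectation,
  `(w−e)/(1−e)` when `w ≥ e`, else `(w−e)/e`. The asymmetric
  normalization maps the index onto [−1, +1] with 0 at random mixing.
  The index is *missing* (not zero) when the type has no members, no
  out-edges, or spans the whole network (`e = 1`).

A descriptive-table quirk: "mean in-degree normalized" (mean in-degree
divided by `n−1`) is algebraically identical to density
(`mean(d_in) = |E|/n`). Published descriptive tables of this design
sometimes print an "in-degree normalized" figure on an unstated scale
that is inconsistent with the printed density; the field is kept as its
own named exposure, computed as mean in-degree/(n−1), and the
discrepancy is documented rather than resolved.

Pearson correlations among metrics use two-sided p-values; pairs with
missing Coleman values are correlated on their complete networks;
constant metrics are reported as missing with a warning.

## Outcome models

Both model families carry a network-level random intercept, which is
what the reported ICC rows of this literature imply; the estimator is
otherwise unstated in the source designs, so:

- **Continuity (linear mixed model).** Outcome and the network metric
  are standardized (sample SD, ddof 1); age (years), sex (male
  indicator), HoNOS (points) and recruitment-service-type dummies stay
  on natural scales, so the metric coefficient is a standardized beta.
  Estimation is REML (statsmodels `MixedLM`); ICC = σ²ᵤ/(σ²ᵤ+σ²ₑ) from
  the REML variance components. **AIC is reported from an ML refit** of
  the same specification, because REML likelihoods are not comparable
  across fixed-effects specifications (and the REML criterion is not an
  AIC in the usual sense). The ICC p-value is a likelihood-ratio test of
  σ²ᵤ = 0 against the 50:50 χ²₀/χ²₁ mixture reference (the boundary
  problem makes the plain χ²₁ conservative).
- **Social integration (random-intercept proportional odds).** The SIX
  total (0–6) is modeled as a cumulative-logit: latent
  `y* = xβ + u_g + logistic`, category c observed between cutpoints
  α_c, α_{c+1}. The marginal likelihood integrates the Gaussian random
  intercept with 21-node Gauss–Hermite quadrature; optimization is
  L-BFGS-B with analytic gradients (cutpoints parameterized as first
  value plus log-increments to keep them ordered; σᵤ as log σ). Start
  values come from the fixed-effects proportional-odds fit
  (statsmodels `OrderedModel`), which is also the null model of the ICC
  likelihood-ratio test. Wald standard errors come from a
  central-difference Hessian of the analytic gradient. Reported
  estimates are odds ratios `exp(β)`; ICC uses the latent logistic
  within-variance π²/3. A "multinomial regression" label in this
  literature paired with a single odds ratio per covariate describes a
  proportional-odds structure, which is what is implemented; a true
  per-category multinomial logit (no random effects) is available as a
  check model (`fit_six_multinomial`).

**Model staging.** Model 1 enters each network metric separately,
always with the four patient-level controls. Model 2 is stepwise:
forward selection among the Model-1-significant metrics (entry p < 0.05,
removal p ≥ 0.05, two-sided Wald; ties broken by smaller p then
alphabetically), controls always retained; for the SIX model a
forced-entry multivariate mode is also exposed because "multivariate"
reporting in this literature is ambiguous between the two. Networks in
which a requested metric is undefined are dropped from that model
(complete case at the network level).

With ~19 clusters, Wald tests carry no small-sample correction
(Kenward–Roger etc. are out of scope); the measured type-I error of the
bivariate continuity test at α = 0.05 under the generator's null is
within the nominal range (see the calibration tests).

## Synthetic-data generator

The generator's defaults are the study conditions, chosen once:

| dial | default | why |
|---|---|---|
| networks | 19 | study design |
| roster size | 11–115, `11 + Beta(1.2,2)·104` | right-skewed over the published range, mean ≈ 50 |
| type mix | published study-average composition | composition realism |
| baseline tie probability | 0.45 | participants-only density near the published ~0.49 |
| within-type factor | 0.6 | mildly heterophilous networks (negative Coleman indices, as observed) |
| hub boost | 2.0 | moderate in-degree centralization with spread across networks |
| often share | 0.5 | both dichotomization rules bite |
| participation rate | 0.52 | published service response rate |
| patients | 80 per network = 8 recruitment clusters × 10 | published sampling plan |
| ACSS intercept / residual SD | 115.6 / 14 | published cohort mean and SD |
| network intercept SD (ACSS) | 2.5 | ICC ≈ 3%, the published order |
| SIX target mean | 3.1 | published cohort mean; cutpoints solved by root finding |
| SIX network intercept SD | 0.6 | latent ICC ≈ 0.10, the published order |
| planted effects | 0.08 SD on continuity (crisis-team homophily), −0.3 log-odds/SD on SIX (size) | effects of the published sign and order, so default runs are non-null |

Mechanics worth knowing:

- ties are drawn independently per ordered pair (a typed inhomogeneous
  random digraph), giving direct, separately controllable density,
  homophily and centralization dials; both dials are monotone by
  construction and verified by test;
- a third of the ties whose target also participated are emitted as the
  mirror-image `referral_received` report, so the reversal convention is
  always exercised; organizational ties are emitted at rate 0.10 and
  must be ignored by construction code;
- patient outcomes: the continuity latent is
  `intercept + Σ βₖ·σ_y·z(metricₖ) + covariate terms + u_net + N(0, σₑ)`
  with `σ_y = √(σ²ᵤ+σ²ₑ)`, so βₖ is interpretable as a standardized
  effect; the latent total is distributed over 31 items in 1..5 that sum
  exactly to the (clipped, rounded) total, with sum-preserving swaps for
  item-level variation. SIX comes from the same proportional-odds
  process the estimator assumes, then is decomposed into components
  (employment ≤ 2, accommodation ≤ 2, family ≤ 1, friendship ≤ 1);
- standardized metric values that are undefined for a network (missing
  Coleman) are mean-imputed to 0 when planting effects;
- determinism: network *i* uses the substream `(seed, i)`; the patient
  stage uses `(seed, 10000019)`; same config ⇒ byte-identical CSVs.

What the generator does **not** emulate, hence what passing tests do not
show about real data: tie reports are conditionally independent (no
reporting styles, no informant bias, no degree heterogeneity beyond one
hub), participation is missing completely at random, item-level ACSS
structure is exchangeable (no subscale factor structure), covariates are
independent of network structure, and patients do not select into
services by severity. Recovery results therefore demonstrate estimator
correctness under the assumed model, not robustness to survey
pathologies.

## Numerical choices and degenerate inputs

- Metrics raise `UndefinedMetricError` below their minimum size (density
  n<2; centralization/clustering n<3; reciprocity with no edges) rather
  than returning 0.
- Composition/dissimilarity inputs must sum to 1 within 1e−6.
- Ordinal likelihood probabilities are floored at 1e−300 for the log and
  1e−12 in gradient denominators; cutpoint ordering is enforced by the
  log-increment parameterization rather than constraints.
- Stepwise ties are broken by (p-value, name); collinear candidates that
  make a fit singular are skipped at that step.
- The linear ICC test returns p = 1 when the likelihood ratio is ≤ 0.
- Pipeline model outputs are deterministic for a fixed seed; tables are
  written at full float precision so re-runs compare byte-for-byte.

## Scales used by the shipped tests

Calibration suites run at the design scale of the emulated study
(19 networks × 80 patients) with 100 replicates for parameter recovery
(planted standardized effect 0.15; planted odds ratio 2.0; planted
latent ICC 0.10) and 200 replicates for type-I error; oracle-equivalence
checks enumerate all directed graphs on 3–4 nodes exhaustively plus 500
random 5-node graphs; pipeline end-to-end tests use reduced studies
(5–6 networks, 40 patients each), since determinism and build-rule
monotonicity do not depend on scale.

## Known limitations

- The ACSS item→subscale map is a synthetic stand-in partition (the
  licensed key is not redistributable); totals are unaffected, subscale
  analyses are structurally correct but substantively placeholder.
- The proportional-odds model assumes a common odds ratio across SIX
  cutpoints; the multinomial check model exists precisely because that
  assumption may fail on real data.
- No small-sample inference corrections; with ~19 clusters, p-values
  near the threshold should be read cautiously.
- No imputation: listwise exclusion of incomplete patient records, as in
  the emulated design.
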