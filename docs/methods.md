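# Methods

## Network measures

All measures are computed within one school's two surveyed grades (the
whole-network boundary); they never cross schools, and an ego's own smoking
status never enters any of its exposure quantities.

**Separation sets.** The degree-k separation set of an ego is defined as
the alters at *directed* geodesic distance exactly k (k = 1, 2, 3),
computed as the non-zero pattern of row *ego* of the adjacency power `X^k`
with the ego and members of lower-degree sets removed. Raw walk counts from
`X^k` would re-include the ego and nearer alters on cycles; the cruder
reading is kept behind `variant="walk"` for comparison. An equivalence test
against breadth-first search runs on random digraphs in the suite. Exposure
at degree k is the percentage of regular smokers in set k, missing when the
set is empty; students with no nominations (empty set 1) therefore carry
missing exposures and drop out of the regression stage, mirroring how
sociometric surveys lose isolates.

**Relative distance to smokers** uses the ego's directed geodesics to every
other student in the school, with unreachable alters substituted at the
maximum finite geodesic observed in that school's network (per school, not
global). It is the mean distance to smoking alters over the mean distance
to all alters, as a percent; exactly 100 when every alter smokes, missing
when none does or when the school has no finite geodesic at all. A
symmetrized-geodesic variant is available (`distance_mode="symmetrized"`)
since nomination data can also be read as undirected contact.

**Coleman homophily index.** At the individual level, with out-degree d,
same-group out-ties m and availability `p = (n_g − 1)/(n − 1)`, the index
is `(m/d − p)/(1 − p)` for `m/d ≥ p` and `(m/d − p)/p` otherwise; undefined
(missing) at d = 0 or when the ego's group is a singleton or the whole
school. The grouping is father's education by default (low / medium / high
/ unknown as its own level). Note a small-sample property that matters for
interpretation: because the downward branch is scaled by `p` and the upward
branch by `1 − p`, the *mean individual* index is negatively biased under
random mixing when out-degrees are small (≈ −0.24 at d ≤ 5 with four
groups). The *network-level* index (`coleman_index_network`), which pools
tie counts within groups before scaling, is unbiased enough for the
random-mixing check and is what the generator's homophily-off sanity test
uses. The individual-level mean is still the reported quantity — it is what
a sociometric survey reports — so the generator's homophily calibration
targets the individual mean.

## Composite SES score

Seven indicators contribute a lowest-band membership each: father's and
mother's education "low", subjective social rank ≤ 5 (of the 1–10 ladder),
father/mother not working, family-affluence ratio ≤ 60% of the national
mean, tenant housing. The count 0–7 is banded 0–4, "5+" for reporting.
Missing-data substitutions before scoring: education → "unknown" (a
retained level that is *never* counted as lowest), rank → the lowest band,
affluence ratio → 1.0 (the national average), working status → working;
every substitution is recorded on the record. Affluence bands are
≤60 / 61–90 / 91–120 / >120% of the national mean with ties going to the
lower band.

## Synthetic cohort generator

The generator's defaults are the study conditions, calibrated once to the
survey's printed marginals and then frozen:

| parameter | default | meaning / calibration anchor |
|---|---|---|
| `n_schools`, `roster_size_range` | 12, (150, 250) | six countries, two grades; 50 schools ≈ 10,000 students at survey scale |
| `target_smoking_prev` | 0.169 | regular-smoking prevalence |
| `target_tried_prev` | 0.466 | ever-tried prevalence |
| `ses_category_probs` | (.326, .289, .193, .116, .055, .021) | composite-score distribution |
| `homophily_strength` | 1.70 | same-parental-education tie bonus (log-odds); tuned so mean individual Coleman ≈ 0.30 |
| `ses_homophily_strength` | 1.00 | tie log-odds penalty per unit deprivation-count gap; tuned so the first-degree exposure gradient across SES bands is ≈ 5–7 percentage points |
| `peer_effect_beta` | log 1.26 | log-OR per 10 percentage points of first-degree exposure |
| `household_base`, `household_smoker_gradient` | 1.2, 0.12 | household smokers ≈ 1.2 at count 0 rising to ≈ 1.8 at count 5 |
| `household_effect` | log 1.50 | log-OR per smoking household member |
| `age_effect`, `sex_effect` | 0.45/yr, log 1.13 | age and sex gradients |
| `country_sd`, `school_ses_sd` | 0.2, 0.35 | country intercept sd; school-level deprivation tilt |
| `missing_rates` | father edu .175, mother edu .148, rank .035, FAS .03, employment .017 | item non-response |
| `out_degree_probs` | (.04, .04, .07, .12, .23, .50) | nominations 0–5, mean ≈ 4 |
| `dependence_mean_regular/tried`, `dependence_alpha` | 11, 1, 0.8 | negative-binomial dependence scores (overall mean ≈ 2.2) |

Each student draws a deprivation count from a school-tilted categorical
distribution (exponential tilt `exp(t·k)`, `t ~ N(0, school_ses_sd)`), and
the count is realised by selecting that many of the seven indicators
(weighted by their population lowest-band shares) to sit in their lowest
band; the remaining values are drawn from the renormalised upper-band
shares. The count itself is the shared latent SES factor — the survey
reports only indicator marginals, so their joint distribution is a design
choice, not an estimate.

Ties are drawn per ego without replacement (Gumbel top-k) with log-weight
`homophily_strength·1[same father-education] −
ses_homophily_strength·|Δcount|`. Missingness is injected *after* tie
formation and smoking assignment, so the mechanisms operate on true values
while downstream code sees survey-like item non-response.

**Smoking fixed point.** Each student receives one uniform draw `u_i`, held
fixed, and smoking is iterated synchronously:
`y_i ← 1{u_i < expit(c + β_ses·count_i + β_hh·hh_i + β_age(age_i−15) +
β_sex·male_i + u_country + β_peer·10·exposure_i(y))}`, with the intercept
`c` re-solved each sweep so the mean predicted prevalence equals its
target, for `n_sweeps` (10) sweeps or until the configuration stops
changing. Holding the thresholds fixed makes the realised configuration
(approximately — a few per-mille of students still flip at sweep 10)
self-consistent with the conditional logistic mechanism, which is what
allows a regression of smoking on *realised* exposure to recover
`peer_effect_beta`. Redrawing fresh Bernoulli noise each sweep, by
contrast, makes realised exposure a noisy proxy of the exposure the
mechanism used (with ≤5 friends the Bernoulli noise dominates), and the
peer coefficient attenuates to a fraction of its value — a classical
errors-in-variables effect, not an estimation bug. Tried-smoking adds a
calibrated extra probability with half-strength gradients on the
non-smokers; dependence scores are negative-binomial (variance
`m + α m²`) conditional on smoking status, zero for never-triers.

The generator is deterministic given `seed` (single PCG64 stream):
identical configs give bit-identical cohorts.

**What the generator does not emulate.** No selection on smoking status in
tie formation (influence only — the cross-sectional analysis cannot
separate the two anyway); no school non-response or student
non-participation; no SES-varying homophily strength (the survey found
high-SES adolescents more homophilous); no country-specific education
systems. Passing tests therefore show the *pipeline* is correct and the
estimators calibrated under the stated mechanism, not that the mechanism is
what generated any real survey.

## Estimation

The mediation sequence is fitted on one estimation sample (listwise
deletion on the union of all M1–M4 terms) so odds ratios are comparable
across models; the log-likelihood is non-decreasing along the nested
sequence by construction. SES enters as band indicators (ref = 0), age as
bands <14 / 14–15 / 16+, exposures per 10 percentage points, relative
distance as a proportion.

Two clustering routes are provided. The default (`method="fe"`) uses
country fixed effects (school fixed effects in M4, absorbing country) with
ordinary ML Wald standard errors. School-level cluster-robust covariances
were evaluated and rejected: the sandwich estimator has rank at most the
number of clusters, so with school dummies in the design it is singular in
exactly the settings that need it, and at 25+ schools it left the
exposure-term calibration unchanged. With only six countries a
random-intercept variance is weakly identified, so the fixed-effects route
is the primary inference path. `method="re"`
fits the variational-Bayes binomial mixed GLM with a country random
intercept (plus a school intercept in M4) and reports the implied variance
components; its posterior is approximate and the components are fragile at
six groups — they are reported for comparability, not inference. The
dependence outcome uses negative-binomial regression (log link, dispersion
estimated by ML); no mixed-effects negative binomial is available, so it is
always fitted with fixed effects. Separated or rank-deficient fits are
returned flagged (`converged=False`) with the diagnostic in `notes`, never
silently.

The homophily × SES interaction enters as Coleman index × linear
deprivation count, giving a single-df Wald test. The exposure "anova"
adjusts band means for age and sex by g-computation from an OLS fit
(predict every student at each band, then average), with the band F-test
from a type-II decomposition; a measure with zero variance short-circuits
to F = 0, p = 1.

## Simulation experiments and their design

* **Peer-effect recovery** is evaluated on cohorts generated with an
  *exogenous* network (both homophily channels and the school tilt off)
  and no household mechanism, so that Model 2 is exactly the
  data-generating conditional: 50 cohorts of ~5,000, Wald CI coverage of
  log 1.26 ≥ 90%. Under the *default* homophilous, school-stratified
  conditions the point estimate stays essentially unbiased (≈ −1% of the
  coefficient) but the z-scores over-disperse (sd ≈ 1.26, coverage ≈ 88%)
  even with cluster-robust errors: school-level smoking equilibria act as
  a social multiplier, so the cross-sectional estimand fluctuates around
  the mechanism parameter — the reflection problem in miniature (and one
  that school-cluster-robust errors do not repair). This is a
  property of cross-sectional peer-effect regressions, documented here as
  a limitation rather than hidden by the experiment design.
* **Attenuation** is checked under the full default mechanism (SES-linked
  household smoking + homophily + peer effect): the lowest-band log-OR
  declines from M1 to M3 in ≥ 80% of replicates. Non-collapsibility of the
  logit works *against* this (adding strong exposure terms inflates
  conditional coefficients), so the observed decline is a real mediation
  signature, not an artefact.
* **Null calibration** of the interaction test uses the default mechanism
  without the household effect (so the fitted M3 is correctly specified
  under the null); 200 replicates, Kolmogorov–Smirnov test of p-value
  uniformity.

Problem sizes in the routine suite (≈ 5,000 students × 50 replicates for
recovery, ≈ 4,000 × 30 for attenuation, ≈ 1,300 × 200 for calibration)
were chosen so each experiment resolves its target property with a
comfortable Monte-Carlo margin; the full 50-school pipeline (~10,000 students) runs in
about ten seconds on one CPU.

## Numerical and degenerate-input conventions

Intercept calibration solves `mean(expit(c + η)) = target` by Brent's
method on [−30, 30]. Undefined per-student measures are `None`/`NaN`, never
sentinel numbers. An edgeless school has no finite geodesic, so relative
distances there are missing. Equal fitted and expected within-group shares
give a Coleman index of exactly 0; all-internal and all-external ties give
exactly ±1. FAS band ties go to the lower band. Cohort files are UTF-8 CSV
with empty cells for missing values; reading validates ids, school
consistency, the ≤5 out-degree cap and self-nominations, and reports the
offending row. Exit codes: 2 for validation failures, 3 for numerical ones.
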