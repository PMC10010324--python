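# Methods

## Overview

The package implements an agnostic drug–cancer screen as a chain of five
stages — synthetic registry, case selection, risk-set sampling, per-pair
exposure modelling, conditional logistic regression, and a two-stage
signal cascade — with every constant of the protocol exposed in
configuration and defaulting to the screening design's values: study
window 2001-01-01 to 2018-12-31, prescriptions observable from 1995,
2-year exposure lag, 10 controls per case, minimum of 25 high-use cases
per pair, cascade thresholds 1.25 and 1.

## Synthetic registry model

The generator is a mechanism for validating the analysis chain, not a
demographic model of any real population.

**Persons.** Sex is Bernoulli(½). Age at mid-study is uniform on a
configurable range (default 20–90 years). Entry into observation is birth,
except for a fraction of immigrants (≈ 20 × the annual migration rate)
whose entry is uniform over the late observation period; exit is
exponential with rate `death_rate + migration_rate` per person-year,
administratively censored shortly after the study end. A standard-normal
latent health score per person is the single unobserved confounder; it is
emitted only to a ground-truth side file (`latent_health.csv`). Education
(four levels: basic, vocational, higher, unknown) is a noisy tertile cut
of `confounder_strength · latent + N(0,1)`, so the education adjustment is
non-vacuous exactly when confounding is switched on.

**Prescriptions.** Per drug, a person becomes an ever-user with
probability `1 − exp(−h · years observed)` where the hazard `h` is
multiplied by `exp(confounder_strength · latent)` for confounder-linked
drugs. A user's fill count is 1 + Poisson with a Gamma-distributed mean
(a negative-binomial-type overdispersed count centred on `mean_fills`),
and fills form a renewal stream with exponential gaps around
`refill_interval_days` (default 90, the usual three-month dispensing
rhythm for chronic therapy — hence 8 fills ≈ 2 years of treatment).
Drugs with `prodromal_boost > 0` add a Poisson burst of extra fills in the
two years before a person's cancer diagnosis, a pure reverse-causation
(protopathic) mechanism used to demonstrate what the exposure lag is for.

**Cancers.** Incidence follows a piecewise-constant hazard over short
calendar periods (default 91 days):

```
λ(t) = λ₀ · exp(α·(age−60) + s·male + c·latent) · Π_d m_d(t)
```

with a planted multiplier per drug `d`: in *categorical* mode
`m_d = RR_high` while the lagged cumulative fill count is ≥ 8, in
*doubling* mode `m_d = RR_doubling^log2(N_lagged)` for users. The lag
applied inside the generator equals the analysis lag (2 years), so the
generative mechanism and the fitted models talk about the same exposure;
the hazard step is kept short because a coarser (yearly) step leaves a
visible attenuation of recovered effects due to the offset between the
period midpoint and the index date. A configurable share of persons gets a
pre-study cancer record (plus a separate share of nonmelanoma skin cancer
records) purely to exercise the exclusion rules. Hospital diagnoses are
Poisson background noise drawn half from Charlson-mapped codes and half
from non-Charlson codes, with intensity tied to the latent score so the
comorbidity adjustment has signal under confounding.

Everything is generated from one `numpy` Generator seeded by
`rng_seed`, and tables are sorted canonically, so equal seeds give
byte-identical output.

## Case–control construction

Cases are persons whose *first-ever* non-NMSC cancer falls in the study
window, aged ≥ 18 at diagnosis, with entry at least 10 calendar years
before it. The attrition report assigns each excluded candidate to the
first failing rule in the fixed order age → prior cancer → migration.

Risk sets are keyed by (sex, birth year); exact birth-year matching is
used because it is the common registry convention and keeps risk sets
large. A control must be resident at the index date (residency is the
half-open interval `[entry, exit)`), migration-clean, adult, and free of
non-NMSC cancer strictly through the index date; future cases qualify
before their own diagnosis and the same person may be drawn for several
sets. Controls are drawn uniformly without replacement by a per-case RNG
stream keyed by (global seed, case identifier), so editing the case list
never reshuffles other sets. A case whose risk set is empty keeps a
0-control set, which is reported but contributes nothing to any
likelihood and is dropped before fitting.

## Exposure and covariates

All windows are half-open `[registry_start, index − lag)`; the window end
is obtained by a calendar-year shift (a Feb 29 anniversary maps to
Feb 28), and exposure and covariates share the same end by construction.
Fill counting takes an exact 7-character ATC code or a 5-character
level-4 prefix; no spacing or consecutiveness of fills is required.
Categories are 0 / 1–2 / 3–7 / 8+; the dose–response parametrization is
`(1[N≥1], log2 N)` with never-use as reference, making the slope the OR
per doubling of cumulative use among ever-users.

The Charlson score uses a compact standard ICD-10 prefix map (longest
prefix wins, so e.g. K704 scores as severe rather than mild liver
disease) with original weights; the two malignancy entities are omitted
because prior-cancer subjects are excluded by design. The map is a data
file (`data/charlson_icd10.csv`) and can be swapped.

## Conditional logistic regression

The conditional likelihood of a 1:m matched set is the softmax
probability of the case row; the log likelihood, gradient and Hessian are
computed exactly and maximized by Newton–Raphson with step-halving from
β = 0 (the likelihood is concave), stopping at gradient max-norm 1e-8
with at most 50 iterations. The covariance is the inverse negative
Hessian at the optimum; CIs are Wald with z = 1.96 on the log-OR scale.

Numerical policy: columns with no within-set variation anywhere carry no
information and are dropped with a warning (coefficients reported NaN); a
coefficient drifting past ±15 log-OR is treated as separation — the fit
is flagged non-converged, reported, and excluded from signal lists; a
singular Hessian triggers one ridge-stabilized retry. CCI enters as a
single numeric covariate; education as three dummies against "basic".

## Screen and cascade

Pairs are enumerated per drug selector (level 5, or level 4 with sibling
substances pooled before counting) against histology-level outcomes
(site, morphology) and optionally site-level outcomes; a pair is fitted
only if at least 25 *cases* are high users — read literally as a
case-side count. The cascade is strict: stage 1 keeps pairs whose
high-use lower 95% limit exceeds 1.25; stage 2 additionally requires the
dose-doubling lower limit to exceed 1. Low-use neutrality (CI containing
1) is an annotation, not a filter. Display rounding of CIs is one
decimal, half away from zero; raw values are always retained.

The bottleneck calculator treats the exposed-case cell as limiting:
`var(log OR) = 1/a + 1/(a·r)` for `a` exposed cases and `r` controls per
case, giving (0.66, 1.51) ≈ 0.7–1.5 at a = 25, r = 10. The multiplicity
figure is `round_to_ten(n_pairs · α)`, e.g. ≈ 680 for 13,577 pairs at
α = 0.05. No multiple-testing correction is applied, by design; the
figure is reported alongside the results.

## Validation experiments and problem sizes

`experiments.py` fixes the two study conditions used by the tests and
`scripts/acceptance.py`:

- **Parameter recovery** — 100 replicate registries of 4,000 persons aged
  45–80, one cancer, one drug planted categorically at RR 3.0 and one in
  doubling mode at RR 1.4 per doubling, no confounding. Checks that the
  respective 95% CIs cover the planted values in ≥ 90% of replicates and
  that the point estimates centre on the truths; this simultaneously
  exercises the claim that risk-set-sampled conditional ORs estimate
  incidence rate ratios.
- **Null calibration** — 3 replicate registries of 12,000 persons with 25
  unrelated drugs and 4 cancers, nothing planted; across the ≥ 200 pairs
  clearing the 25-case rule, the high-use CI should contain 1 about 95%
  of the time and its lower limit should exceed 1 for at most ~5%.

The registries are thousands rather than millions of persons; the wider
CIs that result are the point — coverage, not power, is being tested.
What passing these checks does **not** show: robustness to the bias
structure of real registries (smoking, alcohol and obesity are absent
here as there; confounding by indication is only modelled through one
latent score; prescribing has no seasonality, switching or adherence
dynamics; cancer incidence has no secular trends). A deliberate
demonstration of that gap is included: with a confounder-linked drug and
a confounded cancer, the screen produces inflated ORs — which is exactly
why the cascade output feeds a manual review rather than a verdict.

## Known limitations

- Wald intervals undercover slightly at very small exposed-case counts;
  the 25-case bottleneck rule keeps fits in a regime where this is
  negligible.
- Age matching is exact birth year; no caliper option.
- Dose is fill counts only — no DDD, duration or timing metrics; no
  spline dose–response.
- The Charlson map is a compact representative prefix set, not a full
  national coding list; swap the data file for production use.
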