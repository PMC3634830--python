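# Methods

`gendereffect` studies how the male-vs-female hazard of dying of one's
diagnosed cancer varies with age at diagnosis, and screens cross-sectional
biomarker age profiles for "homology" with that hazard-ratio curve. All
stages run on synthetic data generated in-package, because the registry and
survey extracts the design emulates are access-restricted.

## Cohort model and case selection

A registry record carries age at diagnosis, sex, race (African-American /
Caucasian), a 3-digit ICD-9 primary-site code, tumour class (hematological /
sarcoma / solid), historic stage (distant / localized / regional), follow-up
in months and a cause-specific death flag. Case selection removes, in a
pinned order (the order matters only for tally bookkeeping — a record is
tallied under the first rule it matches):

1. age at diagnosis outside 1–84;
2. death-certificate-only or autopsy-only reporting;
3. multiple primaries;
4. alive with no survival time;
5. sex-specific primary sites — ICD-9 codes 174, 175, 179, 180, 181, 182,
   183, 184, 185, 186, 187 (breast in both sexes, uterus, cervix, ovary,
   vagina/vulva, prostate, testis, penis);
6. any missing required covariate (complete-case analysis).

Follow-up is administratively censored at 60 months; a death exactly at the
horizon remains an event.

## Survival estimation

* **Kaplan–Meier / log-rank** wrap lifelines (product-limit estimator,
  events-before-censorings at ties; two-sample log-rank with 1 df).
* **Cox proportional hazards** is fitted by an in-package Newton solver for
  the Efron-tied partial likelihood (follow-up in whole months makes ties
  pervasive). Convergence: relative log-partial-likelihood change ≤ 1e-9,
  ≤ 100 iterations, step-halving on overshoot; Wald 95% CIs as
  exp(β ± 1.96·se); fits with |β| > 15 or se > 100 are flagged as separated.
  The solver is validated in the tests against brute-force grid maximisation
  of the Efron likelihood on small tied datasets (agreement to 1e-6) and
  against lifelines' `CoxPHFitter` on simulated cohorts (coefficients to
  1e-5). The in-package solver exists because the bootstrap screen in
  `refit` mode performs ~10^5 small stratum fits, which per-fit overhead of
  a general-purpose fitter cannot sustain.
* Model terms default to sex + age + race + tumour type + stage, reference
  levels female / African-American / hematological / distant.
* **Per-age HR sweep**: the same model (age term dropped) is refitted inside
  every single-year age stratum; the male-term HR, CI and Wald p are
  recorded. Strata lacking both sexes, any event, or an identified fit are
  *undefined* (excluded downstream, never imputed). An alternative
  `method="interaction"` fits one pooled model with a linear sex-by-age
  interaction; it is provided for comparison, not as the default, since a
  hump-shaped age effect is not linear.
* **Survival-difference curve**: per age, 100·(S_female(60) − S_male(60))
  from Kaplan–Meier, with the per-age log-rank p; significance at p < 0.05.

## Free Testosterone Index and age profiles

FTI = (TT / SHBG) × 100 with total testosterone and SHBG in consistent
units; non-positive SHBG yields a missing value. A survey variable's age
profile is its per-integer-age median over non-missing values in one sex;
ages without data are omitted.

## Homology screening

Both screens run over the intersection of ages where the HR curve and the
profile are defined (73 ages for a 12–84 survey against a 1–84 registry).

* **Spearman**: rank correlation (average ranks at ties) with the asymptotic
  two-sided p; fewer than 3 overlapping ages, or a constant series, is NA.
* **% homology**: both series are z-scored over their own full series
  (population SD, divisor N — zero spread is degenerate and the replicate
  counts as rejecting). Per bootstrap replicate a common age multiset is
  drawn with replacement, weighted by the survey's per-age sample sizes (the
  size-matching step), and the two-sample Kolmogorov–Smirnov test (exact
  when both sides ≤ 10 points, asymptotic otherwise) is applied to the two
  z-series on that resampled grid. The score is the percentage of replicates
  with KS p ≥ α (α = 0.05; n_boot defaults to 10,000, the tests use 200).

**Why the bootstrap resamples the fixed HR series rather than re-estimating
it.** An alternative (`mode="refit"`) redraws size-matched patients per age
and re-runs the per-age Cox sweep in every replicate. At survey-matched
stratum sizes (~400 patients/age, ~150 events) the per-age log-HR standard
error is ≈ 2/√events ≈ 0.16 — the same magnitude as the spread of the age
signal itself — so the re-estimated series is, distributionally, signal
convolved with equal-sized noise. Simulation shows the KS comparison then
*rejects* a perfectly tracking profile (≈0% homology) while *accepting* a
flat one (≈98%), inverting the score's meaning. The fixed-series bootstrap
keeps the HR side at the precision of the full registry (se ≈ 0.03 at
~14,000 patients/age) and restores the intended discrimination; it is the
default, with `refit` retained for sensitivity analysis.

**Power at series scale.** With ~73 points per side the KS critical distance
at α = 0.05 is ≈ 0.22. A constant-plus-small-noise profile has a roughly
Gaussian z-sample whose population KS distance from the hump-shaped HR
z-distribution is ≈ 0.19, so the test rejects it only ~half the time: a
"flat but noisy" variable can score an intermediate homology. An exactly
constant profile is degenerate under z-scoring and scores 0 by convention.
Interpret intermediate scores (10–80%) with caution; the score separates
cleanly only near its extremes.

## Synthetic data: what it emulates and what it does not

Registry survival times are exponential within covariate cell — any
proportional-hazards generator is valid for testing a semi-parametric
estimator, and the exponential gives closed-form oracles (e.g. the
events/person-time rate ratio within a homogeneous cell recovers a planted
HR). A male of age *a* multiplies the female baseline hazard by
exp(log_hr_by_age[a]); the planted default "hump" is null below 18, rising
to log 1.5 by 25, flat to 41, decaying to null by 61. Covariate hazard
ratios (0.75 Caucasian; 1.61 sarcoma, 1.81 solid; 0.21 localized, 0.84
regional) and the marginal mixes (89.3% Caucasian; 8.3/1.8/89.9% tumour
types; 34.9/44.0/21.1% stages) follow the large-registry convention; the
baseline hazard 0.01166/person-month was calibrated once, in closed form,
so the overall 5-year event fraction is 0.37. Ages are uniform on 1–84
(configurable weights); sex is an even split (configurable); follow-up is
rounded up to whole months to exercise tie handling; 20% of subjects receive
an early uniform censoring time, emulating diagnosis near the registry
cut-off.

Survey values are a sex-specific mean age profile plus additive Gaussian
subject-level noise with SD equal to half the profile's dynamic range —
the order of real biochemical population variation. At the default survey
size (29,314 subjects over ages 12–84) this puts ≈ 0.12 z of noise on each
per-age median, comparable to the residual estimation noise in the HR
series. The generator does not model survey weights, assay detection
limits, cohort age pyramids, non-proportional hazards or competing risks;
a green recovery test therefore establishes correctness of the estimation
pipeline under proportional hazards, not robustness to those features.

Every generator draws from per-stream children of a single master seed
(ages, sexes, covariates, times, censoring, noise), so outputs are
byte-reproducible and enlarging one stream does not perturb the others.

## Numerical conventions

* Wald inference throughout (no likelihood-ratio intervals).
* z-scores use the population SD (divisor N).
* Undefined per-age points propagate as NaN and are dropped from overlaps.
* Significance threshold 0.05 everywhere.
* All bootstrap and simulation seeds are explicit; a pipeline run derives
  per-stage seeds from the config seed via CRC-keyed `SeedSequence` children
  (all below 2^31).

## Known limitations

* Single-year Cox strata need both sexes and events; very sparse ages go
  undefined rather than borrowing strength (no smoothing across ages).
* The homology score's KS has low power at 73-point scale (above).
* The interaction-mode HR curve assumes log-linearity of the sex effect in
  age.
* The exclusion-rule tallies depend on the pinned rule order; totals are
  order-invariant.
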