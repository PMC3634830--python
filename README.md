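# gendereffect

Males die of cancer more often than females, and the excess is not uniform
in age: in registry data the male-vs-female hazard ratio (HR) of
cause-specific death within five years of diagnosis is null in childhood,
rises sharply from ~18, averages ~1.5 through the twenties and thirties, and
decays back to parity by ~61. `gendereffect` is a reusable, tested pipeline
for quantifying that age-resolved "gender effect" and for screening
cross-sectional biomarker age profiles (for example the Free Testosterone
Index, FTI = TT/SHBG × 100) for *homology* with the HR-by-age curve. It is
aimed at biostatisticians and cancer epidemiologists who want the method —
cohort filtering, per-age Cox sweep, Kaplan–Meier differences, Spearman and
bootstrap-KS screening — without access to the restricted registry and
survey extracts, which are replaced by fully seeded synthetic generators.

## The model

For patient *i* with covariates x (sex, age, race, tumour type, stage) the
cause-specific hazard follows a proportional-hazards model
λ(t | x) = λ₀(t)·exp(βᵀx), fitted by the Efron-tied partial likelihood
(registry follow-up is in whole months, so ties are everywhere). The per-age
curve HR(a) is the male coefficient of the same model (age dropped) refitted
in each single-year stratum of age at diagnosis. A survey variable v with
per-age medians v(a) is screened against HR(a) by

* Spearman rank correlation over the common ages, and
* **% homology**: both series are z-scored, (x − μ)/σ, over their own whole
  series; in each of n_boot seeded replicates a common age multiset is drawn
  with replacement (weighted by the survey's per-age sample sizes) and a
  two-sample Kolmogorov–Smirnov test compares the two z-series on that grid;
  the score is the percentage of replicates with KS p ≥ 0.05.

Synthetic registries are exponential-within-cell proportional-hazards draws
with a *planted* HR(a) — so recovery, coverage and calibration are all
testable against ground truth. See `docs/methods.md` for assumptions,
parameter defaults and numerical conventions.

## Worked example

```python
from gendereffect import (GenderEffectAnalysis, RegistrySimSpec,
                          SurveySimSpec, example_survey_panel,
                          fig_hump_log_hr, simulate_registry, simulate_survey)

reg = simulate_registry(RegistrySimSpec(n_patients=200_000, seed=1,
                                        log_hr_by_age=fig_hump_log_hr()))
svy = simulate_survey(SurveySimSpec(n_subjects=29_314, seed=2,
                                    variables=example_survey_panel()))
res = GenderEffectAnalysis(reg, svy, n_boot=200, seed=3).fit()
print(res.summary())
```

prints (abridged):

```
Pooled male-vs-female HR: 1.163
Cox proportional hazards (Efron ties)  n=200000, events=77583 ...
sex[male]   coef 0.1513  HR 1.163  95% CI 1.147-1.18
...
Ages 17-61: male HR 1.318 (n=107314, events=43332)
Ages 62-84: male HR 0.983 (n=54492, events=20232)
HR-by-age: 84 defined ages, 34 significant at p<0.05
Top homology scores:
  fti/male: 94.0% (Spearman R=0.830)
  u_shape/female: 80.0% (Spearman R=-0.494)
```

Read this as: pooled over all ages the planted male excess dilutes to
HR ≈ 1.16, but the 17–61 stratum shows the full ≈ 1.3 excess while 62–84 is
at parity — exactly the planted structure; and among the 12 synthetic survey
variables the FTI analogue (the one constructed to track the planted curve)
dominates both screens. `res.save(outdir)` writes every table (exclusion
report, pooled and stratified Cox tables, HR-by-age and survival-difference
curves, Spearman and homology tables) as CSV plus a JSON run manifest.

The same pipeline is scriptable:

```sh
gendereffect simulate --kind registry -n 100000 --seed 1 --planted hump -o reg.csv
gendereffect filter -i reg.csv -o cohort.csv --report exclusions.csv
gendereffect cox -i cohort.csv -o cox.csv --age-range 17 61
gendereffect hr-sweep -i cohort.csv -o hr.csv
gendereffect run -c config.json          # config-driven end-to-end run
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete synthetic analysis from scratch — registry simulation
with the planted hump, case selection, pooled and age-stratified Cox fits,
the per-age HR sweep, the Kaplan–Meier difference curve and both screens —
writing the artifact tables under `scratch/acceptance_run/` and the results
JSON to `--out`. All randomness derives from `--seed`.
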