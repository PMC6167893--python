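# cohortpath

Survey-weighted life-course analysis of a diabetes-risk genotype, body-mass
-index history and interval type-2-diabetes diagnosis, for cohorts sampled
with a complex (stratified, clustered, weighted) design.

The scientific question it serves: the T allele of rs7903146 (*TCF7L2*)
raises type-2-diabetes risk yet associates with *lower* BMI. Disentangling
whether that inverse association is direct or mediated — through earlier
BMI, or through an earlier diabetes diagnosis and its consequences —
requires modelling genotype, BMI at ages 21/45/65 and period-specific
diagnosis indicators jointly, while honouring the survey design that
produced the data. `cohortpath` provides that machinery for
epidemiologists and statistical geneticists: cohort cleaning with auditable
exclusion accounting, design-based descriptive statistics and GLMs, a
recursive path model with effect decomposition, and a synthetic-cohort
generator so the whole pipeline is testable without restricted data.

## The model

For dosage G ∈ {0,1,2} (count of risk alleles), BMI nodes B₂₁, B₄₅, B₆₅
and period-diagnosis indicators D₁ (ages 22–45), D₂ (ages 46–65), with
covariates **C** (age at exam, sex, education, ancestry proportions,
analysis group) in every equation:

    B21 = α₁ + β_G1·G + γ₁'C + ε₁
    logit P(D1=1) = a₁ + θ_G1·G + θ_B·B21 + δ₁'C
    B45 = α₂ + λ·B21 + β_G2·G + φ·D1 + γ₂'C + ε₂
    logit P(D2=1) = a₂ + θ_G2·G + θ_B·B45 + ψ·D1 + δ₂'C
    B65 = α₃ + λ·B45 + β_G3·G + φ·D2 + γ₃'C + ε₃

Estimation is survey-weighted pseudo-maximum-likelihood per equation
(the joint likelihood of a recursive DAG factorizes), with
Taylor-linearized sandwich variance aggregated over PSUs within strata and
a joint cross-equation covariance for delta-method inference on indirect
effects (products of edge coefficients on the linear-predictor scale).
Age-censored outcomes (a 50-year-old cannot yet have a 46–65 diagnosis)
produce monotone missingness under which the factorized fit is
full-information maximum likelihood; a Monte-Carlo EM handles BMI mediators
missing for other reasons. See `docs/methods.md` for assumptions, defaults
and limitations.

## Worked example

```python
from cohortpath import (ScenarioConfig, simulate_cohort, run_qc,
                        SurveyDesign, fit_weighted_glm)
from cohortpath.simulate import DEFAULT_COVARIATES
from cohortpath.path_model import PathModel, edge_odds_ratio

scenario = ScenarioConfig(seed=7)           # defaults = study conditions
cohort = simulate_cohort(scenario)          # 10 strata x 4 PSUs x 100
qc = run_qc(cohort)
print(qc.ledger.to_text())

full = qc.cohort_full                       # every record stays in variance
design = SurveyDesign.from_frame(full, subpop="analytic")
res = fit_weighted_glm(design, full, "bmi_at_21",
                       ["dosage", *DEFAULT_COVARIATES])
model = PathModel().fit(full, design)
```

Output:

```
rule                               before  excluded    after
pregnancy_amputation                 4000         0     4000
early_diabetes_diagnosis             4000         0     4000
no_usable_height_or_weight           4000        69     3931
missing_analysis_group               3931         0     3931
missing_education                    3931         0     3931
relatedness                          3931         0     3931
final analytic n = 3931

per-allele effect on BMI at 21: -0.25 kg/m^2 (95% CI -0.50, -0.01), n=3887
direct OR, G -> diagnosis in 22-45: 1.25 (95% CI 0.96, 1.64)
indirect G -> BMI45 (sum over 3 mediated paths): +0.186 kg/m^2
```

Reading it: 69 simulated participants lacked any usable height/weight after
cleaning; the per-allele regression recovers the generative −0.20 kg/m²
within its CI; the direct genotype→diagnosis odds ratio recovers the
generative 1.32 within sampling error; and the mediated genotype effect on
mid-life BMI (through early BMI and early diagnosis) is small and positive,
as the generative coefficients imply (the protective direct effect is not
explained by mediation).

A command-line interface mirrors the stages:

```sh
cohortpath simulate --seed 7 --out out/sim
cohortpath qc --cohort out/sim/cohort.csv --out out/qc
cohortpath genetics --cohort out/sim/cohort.csv
cohortpath report --seed 7 --out out/report     # full bundle + manifest
```

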