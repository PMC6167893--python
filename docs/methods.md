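# Methods

`cohortpath` implements a design-based life-course analysis linking a single
biallelic risk variant (additively coded dosage G of the TCF7L2 rs7903146-T
allele), body mass index at ages 21, 45 and 65, and interval indicators of
type-2-diabetes diagnosis in ages 22–45 (D1) and 46–65 (D2), for cohorts
drawn by a two-stage stratified probability design with sampling weights.
Because the motivating cohort data are access-restricted, the package ships
a first-class synthetic-cohort generator whose defaults encode the study
conditions, so every estimator can be validated by parameter recovery
against known generative truths.

## The structural model

The analysis model is a recursive DAG on the temporally ordered nodes
G ≺ BMI21 ≺ D1 ≺ BMI45 ≺ D2 ≺ BMI65:

- BMI nodes are linear regressions; diagnosis nodes are logistic regressions.
- G enters every equation directly; each BMI feeds the diagnosis of the
  immediately following period; each period's diagnosis feeds the next BMI;
  consecutive BMIs carry over; a D1→D2 temporal-dependence edge is
  configurable and on by default (12 edges; 11 with it off).
- The adjustment set — age at examination (age at time of recall), sex,
  education, three continental-ancestry proportions (European reference) and
  genetic analysis group — enters every equation.

With no latent variables the joint likelihood factorizes into
node-given-parents terms, so the survey-weighted pseudo-maximum-likelihood
fit decomposes into per-equation weighted GLMs (the `factorized` method).
Under the monotone missingness that age censoring creates (a node is missing
exactly when the participant is too young for its period) this equals
full-information maximum likelihood under missing-at-random. The `fiml_mc`
method additionally integrates over a continuous BMI mediator that is
missing for other reasons while a descendant is observed: a Monte-Carlo EM
with 64 fixed common random draws per missing value (deterministic given the
seed), expanding each such record into fractionally weighted pseudo-records;
records with more than one integrable missing mediator fall back to
available case. The final covariance for `fiml_mc` reuses the design-based
sandwich on the fractionally weighted augmented data, which treats the EM
weights as fixed; this understates the Monte-Carlo component slightly and is
documented as an approximation.

### Variance estimation

All inference is design-based: Taylor-linearized (sandwich) variance with
score contributions aggregated to PSU totals within strata, treating strata
as sampled with replacement, `V = B⁻¹ M B⁻¹` with `B` the weighted
information and `M = Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)'`.
Joint cross-equation covariance stacks per-equation scores at the PSU level
(block-diagonal `B`, full `M`), which is what the delta method needs for
indirect effects. Subpopulation (domain) estimation zeroes score
contributions outside the domain but never drops records, so item
missingness and analytic-sample exclusions do not distort the design.
Confidence intervals use the normal reference (estimate ± 1.96 SE); a
t reference with (PSUs − strata) degrees of freedom is available via
`SurveyGLM(use_t=True)`. With the default simulated design (10 strata × 4
PSUs, 30 design df) the z reference yields empirical coverage near the low
edge of the 93–97% calibration band; the t switch trades that for slightly
wider intervals. A stratum contributing a single PSU is a hard error by
default (`single_psu="center"` deviates it from the grand mean instead),
because silent centering hides design defects.

### Effect decomposition

Direct effects are edge coefficients; the indirect effect along a path is
the product of its edge coefficients on the linear-predictor scale (the SEM
convention for mixed linear/logistic systems); total = direct + Σ indirect
holds exactly by construction. Standard errors come from the multivariate
delta method with the joint sandwich covariance. For logistic targets the
exponentiated (odds-ratio) forms are attached; odds ratios are
non-collapsible, so products of coefficients through logit nodes are
reported on the log-odds scale only — risk-scale mediation effects are out
of scope. Published results leave ambiguous whether the reported late-period
odds ratio is the conditional D2 edge or a cumulative effect across 22–65;
the package exposes both (the edge OR via `edge_odds_ratio`, the cumulative
total via `effect_decomposition(..., "G", "d2")`) and asserts neither.

## Synthetic cohorts

`simulate_cohort` draws: strata × PSUs × persons with PSU inclusion
probabilities varying across strata (0.3–0.7) and within-PSU person
sampling that oversamples ages ≥ 45 (sampled fraction 0.60 against a
population fraction 0.35); weights are inverse inclusion probabilities.
Genotypes are Hardy–Weinberg draws at risk-allele frequency 0.255. The DAG
defaults are the published per-allele effect sizes used as generative
truths: −0.20 / −0.18 / +0.01 kg/m² on BMI at 21/45/65, log(1.32) on D1,
BMI carryover 0.65, +2.0 kg/m² of prior diagnosis on the next BMI, and 0.10
log-odds per kg/m² of BMI on next-period diagnosis. The late-period genotype
effect on D2 also defaults to log(1.32): the published cumulative 22–65
figure cannot be attributed unambiguously to the conditional edge, so the
unambiguous per-period magnitude is reused. Intercepts and residual SDs
(4.0/3.0/3.0 kg/m²) are calibrated so marginal means track the study
population: BMI ≈ 23.8 → 27.5 → 29.0 kg/m² and period-diagnosis prevalence
≈ 5% (22–45) and ≈ 20% (46–65). PSU-level random intercepts (SD 0.5 kg/m²)
on BMI nodes create genuine within-cluster correlation so the sandwich
variance is actually exercised; they are omitted from the logistic nodes to
keep the marginal logit coefficients equal to the generative ones
(non-collapsibility). A master seed spawns named substreams per stage
(design, covariates, genotype, path, measurement, labs).

The generator stores D1/D2 period indicators drawn from the DAG and derives
a first-diagnosis age from them (uniform within the earliest positive
period — interval indicators do not identify timing). When external data
arrive without D1/D2 columns, `apply_age_censoring` derives them from the
reported diagnosis age; for simulator output it only masks by attained age.
A single reported diagnosis age cannot represent a finite D1→D2 coefficient
(a first diagnosis in 22–45 would force the derived D2 to zero,
quasi-separating the D2 equation), so storing the indicators is what keeps
the generator consistent with the model it feeds.

Self-reported weights carry recall noise (SD 2 kg) and whole-unit rounding;
adult height is fixed per person (baseline measured height stands in for
height at all recalled ages, as in the source design). Recall noise exists
to exercise the cleaning rules: as classical measurement error on mediator
BMIs it attenuates downstream coefficients (reliability ≈ 0.97 at these
SDs), so parameter-recovery runs use a recovery scenario with
`recall_noise_sd=0` and equal weights; whole-unit rounding remains and
contributes bias well below one Monte-Carlo SE at the tested sizes.
Recovery runs also skip the BMI plausibility bounds: with artifact rates at
zero there is nothing to clean, and bound-rejection of genuine tail values
(≈ 2–3% of BMI-at-21 draws fall below 16 kg/m²) is value-dependent
missingness that would bias the very coefficients under test.

What the generator does **not** emulate: household clustering below the
PSU, linkage disequilibrium or multi-variant genetics, ancestry-phenotype
confounding, secular birth-cohort trends, survival selection into old age,
and systematic (non-classical) recall bias. Passing recovery tests
therefore demonstrates estimator correctness under the stated design, not
robustness to those real-data features.

## Weight-history cleaning

Weights convert to whole kilograms (lb ÷ 2.2046, rounded half away from
zero — the published procedure says only "rounded to the whole unit", so
the tie rule is a package choice). Unit confusion (a pounds value entered
as kilograms) is screened by the ratio of a self-report to a reference
weight: within 5% of the lb/kg factor → recode as pounds and flag. The
reference is the concurrent measured weight for the examination
self-report, or the median of the person's other weights for recalled ages;
the tolerance default separates the lb/kg ratio (2.2) from plausible true
weight change between adjacent references. Detection is near-perfect when a
concurrent reference exists and information-limited for recall-only
weights, where true weight change between ages can exceed the tolerance —
the operating-characteristic tests therefore use the concurrent-reference
case. BMI = weight/(height/100)²; values outside 16–70 kg/m² are rejected
(dropped, not clipped), removing the value rather than the person unless no
usable BMI remains. Pregnancy or limb amputation invalidates the baseline
anthropometry only; recalled weights (reported for non-pregnant times)
are retained.

The exclusion cascade runs in a fixed order — pregnancy/amputation leaving
no usable recall, diagnosis before age 22 (diagnoses that young are likely
not type 2), no usable height or self-reported weight, missing analysis
group, missing education, relatedness pruning — with first-rule-wins
accounting in a `FlowLedger` whose arithmetic (`n_after = n_before −
n_excluded`, conservation of persons) is validated on every run.

## Genetics

The Hardy–Weinberg test is the 1-df goodness-of-fit chi-square against
expected proportions at the estimated allele frequency, without continuity
correction — this reproduces the published p = 0.10 from the published
genotype counts; a conditional exact (Levene/Haldane) test is available as
an option since the source does not name its test. Relatedness pruning
flags pairs with 0.35 < π̂ < 0.98 (strict bounds as printed; π̂ ≥ 0.98 is
duplicate-QC territory and out of analysis scope), processes pairs by
descending π̂, drops the member with fewer non-missing weight measurements
(ties: lexicographically larger id), then runs a deterministic reclaim pass
restoring anyone whose flagged partners were all dropped — the kept set
contains no flagged pair and is maximal, though not guaranteed
minimum-removal (pairwise greedy, matching the described procedure, rather
than graph-optimal).

## Numerical choices

- GLM point estimation delegates to statsmodels (`var_weights`
  pseudo-likelihood); IRLS convergence is required, and a diverging linear
  predictor (|η| > 30) or statsmodels' perfect-separation detection raises
  a separation error naming the suspect covariate.
- Rank deficiency on the estimation sample is an error listing the aliased
  columns (pivoted QR).
- Linear-node residual variance is the weighted mean squared residual
  (needed by the Monte-Carlo EM for drawing and density evaluation).
- MC-EM: convergence when the max absolute parameter change is below 1e-6
  (relative), at most 100 iterations; 64 draws per missing value by default.
- Sandwich diagonals are clipped at zero before square roots: with few PSUs
  the estimate is rank-limited and tiny negative diagonals can occur.
- All randomness flows from integer seeds through named `SeedSequence`
  substreams; identical seeds give byte-identical pipeline output.

## Problem sizes used in validation

Recovery runs use 50 replicates of n = 50,000 (acceptance) and 120
replicates of n = 4,000 (monotone-missingness bias check); calibration uses
500 design-based cohorts of n = 4,000 (10 strata × 4 PSUs); the
Monte-Carlo-EM comparison uses 25 replicates of n = 2,880 with 30% of
BMI-at-45 deleted among participants with observed late-life outcomes;
QC operating characteristics use a 500-record fixture with 10% lb-entered
exam self-reports. These sizes give Monte-Carlo SEs small enough for
3-SE bias checks while keeping the suite fast.

## Known limitations

- Indirect effects through logistic mediators are linear-predictor-scale
  products; no risk-scale (counterfactual) mediation.
- No replicate-weight (BRR/jackknife) variance, finite-population
  corrections, or weight calibration.
- The `fiml_mc` covariance ignores Monte-Carlo and E-step-weight
  uncertainty.
- The unit-confusion screen cannot reliably detect lb-entry in recall-only
  weights (no concurrent reference); its guarantees apply to the
  concurrent-reference case.
- Staged outlier rules beyond those stated in the main source text are not
  shipped; the rule engine is extensible.
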