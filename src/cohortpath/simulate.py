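"""Synthetic life-course cohort generator.

Emulates a two-stage stratified probability sample of Hispanic/Latino adults
(21–76 y at examination) with oversampling of ages >= 45, Hardy–Weinberg
genotypes at a single biallelic risk variant, and a recursive generative DAG
over genotype dosage G, BMI at ages 21/45/65, and interval type-2-diabetes
diagnosis indicators D1 (ages 22–45) and D2 (ages 46–65):

    BMI21 ~ linear(G, covariates)
    D1    ~ logit(G, BMI21, covariates)
    BMI45 ~ linear(G, BMI21, D1, covariates)
    D2    ~ logit(G, BMI45, D1, covariates)
    BMI65 ~ linear(G, BMI45, D2, covariates)

Default path coefficients are the study's published effect sizes (e.g.
-0.20 kg/m^2 per risk allele on BMI at 21, odds ratio 1.32 per allele on
diagnosis in ages 22–45), so simulated cohorts serve as ground truth for
parameter-recovery testing of the estimation modules. Self-reported weights
carry recall noise and whole-unit rounding; adult height is fixed per person
across ages. A master seed spawns named substreams so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioConfig",
    "ArtifactRates",
    "ConfigError",
    "simulate_cohort",
    "apply_age_censoring",
    "censoring_violations",
    "inject_artifacts",
    "InjectionResult",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_kinship_tsv",
    "read_kinship_tsv",
    "NODE_COLUMNS",
    "DEFAULT_COVARIATES",
]

LB_PER_KG = 2.2046

#: canonical DAG node name -> cohort column
NODE_COLUMNS = {
    "G": "dosage",
    "bmi21": "bmi_at_21",
    "d1": "D1",
    "bmi45": "bmi_at_45",
    "d2": "D2",
    "bmi65": "bmi_at_65",
}

#: adjustment set used in every published model: age at exam (age at recall),
#: sex, education, continental ancestry proportions (European reference) and
#: genetic analysis group.
DEFAULT_COVARIATES = [
    "age_exam",
    "female",
    "education",
    "anc_afr",
    "anc_nam",
    "anc_sam",
    "analysis_group",
]

ANALYSIS_GROUPS = [
    "central_american",
    "cuban",
    "dominican",
    "mexican",
    "puerto_rican",
    "south_american",
]
# sampled-frequency analogue of the published group distribution
GROUP_PROBS = [0.08, 0.27, 0.09, 0.33, 0.17, 0.06]


class ConfigError(ValueError):
    """Scenario configuration violates its invariants."""


@dataclass
class ScenarioConfig:
    """Generative scenario: design geometry, genetics, path coefficients.

    Path-coefficient defaults are the published per-allele effect sizes used
    as simulation truths; residual SDs and intercepts are calibrated so the
    marginal BMI means and period-diagnosis prevalences approximate the study
    population (BMI ~24 at 21 y rising to ~29 at 65 y; ~5% diagnosed by 45,
    ~20% diagnosed in 46–65).
    """

    # design
    n_strata: int = 10
    psus_per_stratum: int = 4
    persons_per_psu: int = 100
    oversample_age45: float = 0.60  # sampled fraction aged >= 45
    pop_frac_age45: float = 0.35    # population fraction aged >= 45
    equal_weights: bool = False
    # genetics
    risk_allele_freq: float = 0.255
    # linear paths (kg/m^2)
    beta_G_bmi21: float = -0.20
    beta_G_bmi45: float = -0.18
    beta_G_bmi65: float = 0.01
    beta_bmi_carryover: float = 0.65
    beta_D_bmi: float = 2.0  # diagnosis in previous period -> next BMI
    # log-odds paths
    theta_G_D1: float = math.log(1.32)
    theta_G_D2: float = math.log(1.32)
    theta_bmi_D: float = 0.10    # per kg/m^2 on next-period diagnosis
    theta_D1_D2: float = 0.5
    # intercepts
    alpha_bmi21: float = 24.5
    alpha_bmi45: float = 12.7
    alpha_bmi65: float = 11.4
    alpha_D1: float = -5.16
    alpha_D2: float = -4.0
    # residual structure
    sd_bmi21: float = 4.0
    sd_bmi45: float = 3.0
    sd_bmi65: float = 3.0
    sd_psu_bmi: float = 0.5      # PSU-level random intercept on BMI nodes
    recall_noise_sd: float = 2.0  # kg, on self-reported historical weights
    # covariate effects
    beta_age_bmi: float = 0.02       # per year of age at recall, on BMI nodes
    beta_female_bmi: float = -0.8
    beta_edu_bmi: float = -0.5
    theta_age_d: float = 0.0
    theta_female_d: float = -0.2
    theta_edu_d: float = -0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.risk_allele_freq < 1:
            raise ConfigError("risk_allele_freq must be in (0, 1)")
        for name in ("sd_bmi21", "sd_bmi45", "sd_bmi65"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sd_psu_bmi < 0 or self.recall_noise_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        for name in ("n_strata", "psus_per_stratum", "persons_per_psu"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.oversample_age45 < 1 or not 0 < self.pop_frac_age45 < 1:
            raise ConfigError("age-45 fractions must be in (0, 1)")
        if abs(self.beta_bmi_carryover) >= 1.5:
            raise ConfigError("beta_bmi_carryover is degenerate (|value| >= 1.5)")

    @property
    def n_total(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.persons_per_psu

    def truth_edges(self) -> dict[tuple[str, str], float]:
        """Generative coefficient for every DAG edge, keyed by node names."""
        return {
            ("G", "bmi21"): self.beta_G_bmi21,
            ("G", "d1"): self.theta_G_D1,
            ("G", "bmi45"): self.beta_G_bmi45,
            ("G", "d2"): self.theta_G_D2,
            ("G", "bmi65"): self.beta_G_bmi65,
            ("bmi21", "d1"): self.theta_bmi_D,
            ("bmi21", "bmi45"): self.beta_bmi_carryover,
            ("d1", "bmi45"): self.beta_D_bmi,
            ("d1", "d2"): self.theta_D1_D2,
            ("bmi45", "d2"): self.theta_bmi_D,
            ("bmi45", "bmi65"): self.beta_bmi_carryover,
            ("d2", "bmi65"): self.beta_D_bmi,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str) -> "ScenarioConfig":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source, encoding="utf-8") as fh:
                d = json.load(fh)
        return cls(**d)


def _stage_rngs(seed: int, stages: list[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(stages))
    return {name: np.random.default_rng(c) for name, c in zip(stages, children)}


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Draw one cohort from the scenario's design and generative DAG.

    Returns one row per sampled participant with design fields, covariates,
    genotype, latent-node BMIs re-expressed as (noisy, rounded) self-reported
    weights, interval diagnosis indicators already age-censored, and
    descriptive glycemic labs. True (pre-noise) node BMIs are retained in
    ``true_bmi21/45/65`` columns for testing.
    """
    config.validate()
    rngs = _stage_rngs(
        config.seed,
        ["design", "covariates", "genotype", "path", "measurement", "labs"],
    )
    n = config.n_total
    rng_d = rngs["design"]

    # --- design: strata, PSUs, inclusion probabilities --------------------
    strata = np.repeat(np.arange(1, config.n_strata + 1), config.psus_per_stratum * config.persons_per_psu)
    psu_within = np.tile(
        np.repeat(np.arange(config.psus_per_stratum), config.persons_per_psu), config.n_strata
    )
    psu = strata * 1000 + psu_within  # globally unique, nested in stratum
    if config.equal_weights:
        p_psu = np.full(config.n_strata, 0.5)
    else:
        p_psu = np.linspace(0.3, 0.7, config.n_strata)
    f = config.pop_frac_age45 if config.equal_weights else config.oversample_age45
    F = config.pop_frac_age45
    p_young = 0.25
    p_old = p_young * (f * (1 - F)) / ((1 - f) * F)
    is_old = rng_d.random(n) < f
    p_sel = np.where(is_old, p_old, p_young) * p_psu[strata - 1]
    weights = 1.0 / p_sel

    rng_c = rngs["covariates"]
    age = np.where(is_old, rng_c.uniform(45.0, 76.0, n), rng_c.uniform(21.0, 45.0, n))
    female = (rng_c.random(n) < 0.5).astype(int)
    education = (rng_c.random(n) < 0.69).astype(int)
    ancestry = rng_c.dirichlet([6.0, 1.0, 4.0, 2.0], size=n)  # eur, afr, nam, sam
    group = rng_c.choice(ANALYSIS_GROUPS, size=n, p=GROUP_PROBS)
    height = np.where(female == 1, rng_c.normal(158.0, 6.0, n), rng_c.normal(170.0, 6.0, n))
    height = np.clip(height, 140.0, 200.0)

    # --- genotype in HWE proportions --------------------------------------
    dosage = rngs["genotype"].binomial(2, config.risk_allele_freq, size=n)
    genotype = np.array(["CC", "CT", "TT"])[dosage]

    # --- generative DAG ----------------------------------------------------
    rng_p = rngs["path"]
    cov_bmi = (
        config.beta_age_bmi * (age - 45.0)
        + config.beta_female_bmi * female
        + config.beta_edu_bmi * education
    )
    cov_d = (
        config.theta_age_d * (age - 45.0)
        + config.theta_female_d * female
        + config.theta_edu_d * education
    )
    psu_ids, psu_index = np.unique(psu, return_inverse=True)
    def psu_effect() -> np.ndarray:
        u = rng_p.normal(0.0, config.sd_psu_bmi, size=len(psu_ids))
        return u[psu_index]

    bmi21 = (
        config.alpha_bmi21 + config.beta_G_bmi21 * dosage + cov_bmi
        + psu_effect() + rng_p.normal(0.0, config.sd_bmi21, n)
    )
    p_d1 = _expit(config.alpha_D1 + config.theta_G_D1 * dosage + config.theta_bmi_D * bmi21 + cov_d)
    d1 = (rng_p.random(n) < p_d1).astype(float)
    bmi45 = (
        config.alpha_bmi45 + config.beta_bmi_carryover * bmi21
        + config.beta_G_bmi45 * dosage + config.beta_D_bmi * d1 + cov_bmi
        + psu_effect() + rng_p.normal(0.0, config.sd_bmi45, n)
    )
    p_d2 = _expit(
        config.alpha_D2 + config.theta_G_D2 * dosage + config.theta_bmi_D * bmi45
        + config.theta_D1_D2 * d1 + cov_d
    )
    d2 = (rng_p.random(n) < p_d2).astype(float)
    bmi65 = (
        config.alpha_bmi65 + config.beta_bmi_carryover * bmi45
        + config.beta_G_bmi65 * dosage + config.beta_D_bmi * d2 + cov_bmi
        + psu_effect() + rng_p.normal(0.0, config.sd_bmi65, n)
    )

    # first diagnosis age: uniform within the earliest positive period
    # (interval indicators identify only the period, not the timing)
    dx_age = np.full(n, np.nan)
    m1 = d1 == 1
    dx_age[m1] = rng_p.uniform(22.0, 45.0, int(m1.sum()))
    m2 = (d1 == 0) & (d2 == 1)
    dx_age[m2] = rng_p.uniform(46.0, 65.0, int(m2.sum()))
    dx_age = np.where(dx_age <= age, dx_age, np.nan)  # future onsets unreported

    # --- measurement layer --------------------------------------------------
    rng_m = rngs["measurement"]
    h2 = (height / 100.0) ** 2
    # BMI at exam: piecewise interpolation along the latent node trajectory
    bmi_exam = np.where(
        age <= 45.0,
        bmi21 + (bmi45 - bmi21) * (age - 21.0) / 24.0,
        np.where(
            age <= 65.0,
            bmi45 + (bmi65 - bmi45) * (age - 45.0) / 20.0,
            bmi65 + 0.03 * (age - 65.0),
        ),
    ) + rng_m.normal(0.0, 0.5, n)
    measured_weight = np.round(bmi_exam * h2, 1)
    self_weight_exam = np.round(measured_weight + 0.23 + rng_m.normal(0.0, 1.0, n))

    def recalled(bmi_node: np.ndarray) -> np.ndarray:
        w = bmi_node * h2 + rng_m.normal(0.0, config.recall_noise_sd, n)
        return np.round(w)

    weight_21 = recalled(bmi21)
    weight_45 = recalled(bmi45)
    weight_65 = recalled(bmi65)

    # --- descriptive glycemic labs (plumbing for classification tables) ----
    rng_l = rngs["labs"]
    diagnosed = ~np.isnan(dx_age)
    fg = np.where(diagnosed, rng_l.normal(145.0, 30.0, n), rng_l.normal(94.0, 9.0, n))
    fg = np.clip(fg, 65.0, 400.0)
    ins = np.exp(rng_l.normal(2.4, 0.5, n) + 0.25 * diagnosed)
    ogtt = np.where(diagnosed, np.nan, np.clip(rng_l.normal(113.0, 25.0, n), 50.0, 400.0))
    hba1c = np.where(diagnosed, rng_l.normal(7.4, 1.2, n), rng_l.normal(5.45, 0.3, n))
    hba1c = np.clip(hba1c, 4.0, 14.0)
    meds = (diagnosed & (rng_l.random(n) < 0.7)).astype(int)

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "stratum": strata,
            "psu": psu,
            "sampling_weight": weights,
            "female": female,
            "age_exam": age,
            "education": education,
            "anc_eur": ancestry[:, 0],
            "anc_afr": ancestry[:, 1],
            "anc_nam": ancestry[:, 2],
            "anc_sam": ancestry[:, 3],
            "analysis_group": group,
            "genotype": genotype,
            "dosage": dosage.astype(float),
            "height_cm": np.round(height),
            "measured_weight_kg": measured_weight,
            "self_weight_exam": self_weight_exam,
            "weight_at_21": weight_21,
            "weight_at_45": weight_45,
            "weight_at_65": weight_65,
            "diabetes_diagnosis_age": dx_age,
            "D1": d1,
            "D2": d2,
            "fasting_glucose": np.round(fg, 1),
            "fasting_insulin": np.round(ins, 1),
            "ogtt_glucose": np.round(ogtt, 1),
            "hba1c_pct": np.round(hba1c, 2),
            "on_diabetes_meds": meds,
            "pregnant": np.zeros(n, dtype=int),
            "amputation": np.zeros(n, dtype=int),
            "true_bmi21": bmi21,
            "true_bmi45": bmi45,
            "true_bmi65": bmi65,
        }
    )
    return apply_age_censoring(df)


def apply_age_censoring(cohort: pd.DataFrame) -> pd.DataFrame:
    """Enforce by-design missingness of incomplete age periods.

    D1 (diagnosis in ages 22–45) is defined only for participants aged >= 45
    at examination, D2 (ages 46–65) only for those aged >= 65; recalled
    weights at 45/65 are likewise undefined below those ages. If D1/D2
    columns are absent (external data), they are first derived from
    ``diabetes_diagnosis_age``. Records whose diagnosis age exceeds the exam
    age are flagged in ``inconsistent_diagnosis``.
    """
    df = cohort.copy()
    age = pd.to_numeric(df["age_exam"]).to_numpy(dtype=float)
    dx = pd.to_numeric(df.get("diabetes_diagnosis_age", np.nan)).to_numpy(dtype=float)

    if "D1" not in df.columns:
        df["D1"] = ((dx >= 22) & (dx <= 45)).astype(float)
    if "D2" not in df.columns:
        df["D2"] = ((dx >= 46) & (dx <= 65)).astype(float)
    df["D1"] = pd.to_numeric(df["D1"]).astype(float)
    df["D2"] = pd.to_numeric(df["D2"]).astype(float)
    df.loc[age < 45, "D1"] = np.nan
    df.loc[age < 65, "D2"] = np.nan
    for a, col in ((45, "weight_at_45"), (65, "weight_at_65")):
        if col in df.columns:
            df.loc[age < a, col] = np.nan
    df["inconsistent_diagnosis"] = (~np.isnan(dx)) & (dx > age)
    return df


def censoring_violations(cohort: pd.DataFrame) -> int:
    """Count records violating the age-censoring invariants (0 when clean)."""
    age = pd.to_numeric(cohort["age_exam"]).to_numpy(dtype=float)
    d1 = pd.to_numeric(cohort["D1"]).to_numpy(dtype=float)
    d2 = pd.to_numeric(cohort["D2"]).to_numpy(dtype=float)
    bad = ((age < 45) & ~np.isnan(d1)) | ((age < 65) & ~np.isnan(d2))
    for a, col in ((45, "weight_at_45"), (65, "weight_at_65")):
        if col in cohort.columns:
            w = pd.to_numeric(cohort[col]).to_numpy(dtype=float)
            bad |= (age < a) & ~np.isnan(w)
    return int(bad.sum())


@dataclass
class ArtifactRates:
    """Per-record corruption rates for QC stress inputs (0 = no-op)."""

    unit_confusion: float = 0.0   # self-reported weight stored in lb
    pregnancy: float = 0.0
    extreme_bmi: float = 0.0      # weight pushed outside plausible BMI bounds
    early_diagnosis: float = 0.0  # diagnosis age < 22
    kinship: float = 0.0          # fraction of records paired as close relatives
    #: which self-reported weight columns unit confusion may hit
    unit_confusion_columns: tuple[str, ...] = (
        "self_weight_exam",
        "weight_at_21",
        "weight_at_45",
        "weight_at_65",
    )

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if f_.name == "unit_confusion_columns":
                continue
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"artifact rate {f_.name} must be in [0, 1]")


class InjectionResult(NamedTuple):
    cohort: pd.DataFrame
    kinship: pd.DataFrame  # columns id1, id2, pi_hat
    log: pd.DataFrame      # columns id, kind, column, truth


WEIGHT_COLS = ["self_weight_exam", "weight_at_21", "weight_at_45", "weight_at_65"]


def inject_artifacts(
    cohort: pd.DataFrame, rates: ArtifactRates, seed: int
) -> InjectionResult:
    """Corrupt a cohort with the QC-relevant artifact classes.

    Unit confusion re-expresses a self-reported weight in pounds
    (``round(kg * 2.2046)``); the pre-corruption truth is retained in
    ``truth_<column>`` and in the returned log so detector sensitivity and
    false-flag rates can be scored exactly.
    """
    rates.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))
    df = cohort.copy()
    entries: list[tuple[str, str, str, float]] = []
    n = len(df)

    if rates.unit_confusion > 0:
        for col in rates.unit_confusion_columns:
            if col not in df.columns:
                continue
            vals = pd.to_numeric(df[col]).to_numpy(dtype=float)
            eligible = np.flatnonzero(~np.isnan(vals))
            hit = eligible[rng.random(len(eligible)) < rates.unit_confusion]
            if len(hit) == 0:
                continue
            tcol = f"truth_{col}"
            if tcol not in df.columns:
                df[tcol] = np.nan
            df.loc[df.index[hit], tcol] = vals[hit]
            df.loc[df.index[hit], col] = np.round(vals[hit] * LB_PER_KG)
            for i in hit:
                entries.append((df["id"].iloc[i], "unit_confusion", col, vals[i]))

    if rates.pregnancy > 0:
        women = np.flatnonzero(df["female"].to_numpy() == 1)
        hit = women[rng.random(len(women)) < rates.pregnancy]
        df.loc[df.index[hit], "pregnant"] = 1
        entries.extend((df["id"].iloc[i], "pregnancy", "pregnant", 0.0) for i in hit)

    if rates.extreme_bmi > 0:
        vals = pd.to_numeric(df["weight_at_21"]).to_numpy(dtype=float)
        eligible = np.flatnonzero(~np.isnan(vals))
        hit = eligible[rng.random(len(eligible)) < rates.extreme_bmi]
        if len(hit):
            tcol = "truth_weight_at_21"
            if tcol not in df.columns:
                df[tcol] = np.nan
            df.loc[df.index[hit], tcol] = vals[hit]
            factor = np.where(rng.random(len(hit)) < 0.5, 0.3, 3.0)
            df.loc[df.index[hit], "weight_at_21"] = np.round(vals[hit] * factor)
            for i, v in zip(hit, vals[hit]):
                entries.append((df["id"].iloc[i], "extreme_bmi", "weight_at_21", v))

    if rates.early_diagnosis > 0:
        hit = np.flatnonzero(rng.random(n) < rates.early_diagnosis)
        truth = pd.to_numeric(df["diabetes_diagnosis_age"]).to_numpy(dtype=float)
        df.loc[df.index[hit], "diabetes_diagnosis_age"] = np.round(
            rng.uniform(10.0, 21.0, len(hit)), 1
        )
        for i in hit:
            entries.append((df["id"].iloc[i], "early_diagnosis", "diabetes_diagnosis_age", truth[i]))

    pairs: list[tuple[str, str, float]] = []
    if rates.kinship > 0:
        n_pairs = int(round(rates.kinship * n / 2))
        if n_pairs > 0:
            chosen = rng.choice(n, size=min(2 * n_pairs, n - n % 2), replace=False)
            for a, b in zip(chosen[0::2], chosen[1::2]):
                pi_hat = float(rng.uniform(0.4, 0.6))
                pairs.append((df["id"].iloc[a], df["id"].iloc[b], pi_hat))
                entries.append((df["id"].iloc[a], "kinship", "pi_hat", pi_hat))

    kin = pd.DataFrame(pairs, columns=["id1", "id2", "pi_hat"])
    log = pd.DataFrame(entries, columns=["id", "kind", "column", "truth"])
    return InjectionResult(df, kin, log)


# --- I/O ---------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_kinship_tsv(kinship: pd.DataFrame, path) -> None:
    kinship[["id1", "id2", "pi_hat"]].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_kinship_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
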