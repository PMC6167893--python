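"""End-to-end orchestration: simulate/load -> QC -> genetics -> survey
regression -> path model -> report bundle.

All stages are deterministic given the seed; outputs are JSON/CSV/plain text
with stable key and column order, plus a manifest recording the seed,
package version and SHA-256 hashes of the inputs. Variance calculations use
the complex sampling information of the entire cohort with the analytic
sample as estimation subpopulation, mirroring design-based subpopulation
practice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genetics import genotype_counts_from_dosage, hwe_test, additive_code, read_variant_vcf
from .glycemia import classify_glycemia_frame
from .path_model import PathModel, default_path_spec, edge_odds_ratio, effect_decomposition
from .qc import QCRuleSet, run_qc
from .simulate import (
    ArtifactRates,
    ConfigError,
    DEFAULT_COVARIATES,
    ScenarioConfig,
    apply_age_censoring,
    inject_artifacts,
    read_cohort_csv,
    read_kinship_tsv,
    simulate_cohort,
)
from .survey import SurveyDesign, fit_weighted_glm, adjusted_genotype_means

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "render_tables",
    "glycemic_strata",
]

BMI_OUTCOMES = ["bmi_measured", "bmi_self_exam", "bmi_at_21", "bmi_at_45", "bmi_at_65"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, rule overrides and toggles for one pipeline run.

    Exactly one of ``scenario`` (simulate) or ``cohort_path`` (load) must be
    provided.
    """

    scenario: ScenarioConfig | None = None
    cohort_path: str | None = None
    kinship_path: str | None = None
    vcf_path: str | None = None
    variant_id: str = "rs7903146"
    risk_allele: str = "T"
    ruleset: QCRuleSet = field(default_factory=QCRuleSet)
    artifact_rates: ArtifactRates | None = None
    include_d1_d2: bool = True
    path_method: str = "factorized"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if (self.scenario is None) == (self.cohort_path is None):
            raise ConfigError("provide exactly one of scenario or cohort_path")


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def glycemic_strata(df: pd.DataFrame) -> pd.DataFrame:
    """Mutually exclusive glycemic strata at examination.

    ``prior_diagnosis`` (reported before exam), ``undiagnosed_t2d`` (meets
    criteria at exam without prior report), ``impaired_fasting_glucose``,
    ``normoglycemic``; plus the overlapping ``on_medication`` indicator.
    The first four partition every classified record.
    """
    cls = classify_glycemia_frame(df)
    dx = pd.to_numeric(df.get("diabetes_diagnosis_age", np.nan)).to_numpy(dtype=float)
    prior = ~np.isnan(dx)
    undiag = cls["t2d_at_exam"].to_numpy() & ~prior
    ifg = (cls["impaired_fasting_glucose"].to_numpy() == 1) & ~prior & ~undiag
    normo = ~(prior | undiag | ifg)
    meds = pd.to_numeric(df.get("on_diabetes_meds", 0)).fillna(0).to_numpy(dtype=float) >= 1
    return pd.DataFrame(
        {
            "prior_diagnosis": prior,
            "undiagnosed_t2d": undiag,
            "impaired_fasting_glucose": ifg,
            "normoglycemic": normo,
            "on_medication": meds,
        },
        index=df.index,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the report bundle (also written to
    ``config.outdir`` when set). Deterministic given ``config.seed``."""
    config.validate()
    bundle: dict = {}
    manifest: dict = {"package": "cohortpath", "version": __version__, "seed": config.seed,
                      "inputs": {}}
    stage = "input"
    try:
        if config.scenario is not None:
            scenario = dataclasses.replace(config.scenario, seed=config.seed)
            cohort = simulate_cohort(scenario)
            kinship = pd.DataFrame(columns=["id1", "id2", "pi_hat"])
            manifest["inputs"]["scenario_sha256"] = hashlib.sha256(
                scenario.to_json().encode()
            ).hexdigest()
            if config.artifact_rates is not None:
                cohort, kin2, _ = inject_artifacts(cohort, config.artifact_rates, config.seed)
                kinship = pd.concat([kinship, kin2], ignore_index=True)
        else:
            cohort = apply_age_censoring(read_cohort_csv(config.cohort_path))
            manifest["inputs"]["cohort_sha256"] = _sha256_file(config.cohort_path)
            kinship = pd.DataFrame(columns=["id1", "id2", "pi_hat"])
            if config.kinship_path:
                kinship = read_kinship_tsv(config.kinship_path)
                manifest["inputs"]["kinship_sha256"] = _sha256_file(config.kinship_path)
            if config.vcf_path:
                geno = read_variant_vcf(config.vcf_path, config.variant_id)
                manifest["inputs"]["vcf_sha256"] = _sha256_file(config.vcf_path)
                dosage = {
                    s: additive_code(gt, config.risk_allele) if gt is not None else float("nan")
                    for s, gt in geno.items()
                }
                cohort["dosage"] = cohort["id"].map(dosage)

        stage = "qc"
        qc = run_qc(cohort, kinship if len(kinship) else None, config.ruleset)
        bundle["flow_ledger"] = json.loads(qc.ledger.to_json())
        full = qc.cohort_full

        stage = "genetics"
        counts = genotype_counts_from_dosage(full.loc[full["analytic"], "dosage"])
        chi2, pval = hwe_test(counts)
        bundle["hwe"] = {
            "n_ref_hom": counts.n_ref_hom,
            "n_het": counts.n_het,
            "n_risk_hom": counts.n_risk_hom,
            "risk_allele_freq": counts.risk_allele_freq,
            "chi2": chi2,
            "p_value": pval,
        }

        stage = "survey_models"
        design = SurveyDesign.from_frame(full)
        analytic = full["analytic"].to_numpy()
        rows = []
        for outcome in BMI_OUTCOMES:
            res = fit_weighted_glm(
                design, full, outcome, ["dosage", *config.covariates], subpop=analytic
            )
            j = res.names.index("dosage")
            ci = res.conf_int()[j]
            rows.append(
                {
                    "outcome": outcome,
                    "n": res.n_used,
                    "estimate": float(res.params[j]),
                    "se": float(res.bse[j]),
                    "ci_low": float(ci[0]),
                    "ci_high": float(ci[1]),
                    "p_value": float(res.pvalues[j]),
                }
            )
        bundle["per_allele_bmi_models"] = rows

        desc_covs = ["age_exam", "female", "anc_afr", "anc_nam", "anc_sam"]
        means_rows = []
        for outcome in ["bmi_measured", "bmi_self_exam", "measured_weight_kg", "fasting_glucose"]:
            try:
                am = adjusted_genotype_means(design, full, outcome, desc_covs, subpop=analytic)
            except ValueError:
                continue
            means_rows.append(
                {
                    "outcome": outcome,
                    "mean_ref_hom": am.means[0],
                    "mean_het": am.means[1],
                    "mean_risk_hom": am.means[2],
                    "se_ref_hom": am.ses[0],
                    "se_het": am.ses[1],
                    "se_risk_hom": am.ses[2],
                    "joint_p": am.joint_p,
                    "n": am.n_used,
                }
            )
        bundle["genotype_means"] = means_rows

        strata = glycemic_strata(full)
        strat_rows = []
        for name in ["prior_diagnosis", "undiagnosed_t2d", "impaired_fasting_glucose",
                     "normoglycemic", "on_medication"]:
            sub = analytic & strata[name].to_numpy()
            if sub.sum() < 50:
                continue
            for outcome in ["bmi_measured", "bmi_self_exam"]:
                try:
                    res = fit_weighted_glm(
                        design, full, outcome, ["dosage", *config.covariates], subpop=sub
                    )
                except Exception:
                    continue
                j = res.names.index("dosage")
                strat_rows.append(
                    {
                        "stratum": name,
                        "outcome": outcome,
                        "n": res.n_used,
                        "estimate": float(res.params[j]),
                        "se": float(res.bse[j]),
                        "p_value": float(res.pvalues[j]),
                    }
                )
        bundle["stratified_bmi_models"] = strat_rows

        stage = "path_model"
        spec = default_path_spec(
            include_d1_d2=config.include_d1_d2,
            covariates=config.covariates,
            method=config.path_method,
        )
        model = PathModel(spec=spec, method=config.path_method)
        model.fit(full, design.replace_subpop(analytic))
        fit = model.result_
        bundle["path_model"] = {
            "method": fit.method,
            "n_missing_genotype": fit.n_missing_genotype,
            "n_by_node": fit.n_by_node,
            "equations": fit.summary_frame().to_dict(orient="records"),
        }
        ors = {}
        for edge in [("G", "d1"), ("G", "d2")]:
            e = edge_odds_ratio(model, edge)
            ors["->".join(edge)] = {
                "log_odds": e.estimate,
                "se": e.se,
                "odds_ratio": e.exponentiated[0],
                "ci_low": e.exponentiated[1],
                "ci_high": e.exponentiated[2],
            }
        bundle["edge_odds_ratios"] = ors
        decomp = []
        for target in ["d1", "bmi45", "d2", "bmi65"]:
            for eff in effect_decomposition(model, "G", target):
                decomp.append(
                    {
                        "source": eff.source,
                        "target": eff.target,
                        "kind": eff.kind,
                        "path": "->".join(eff.path),
                        "estimate": eff.estimate,
                        "se": eff.se,
                        "ci_low": eff.ci[0],
                        "ci_high": eff.ci[1],
                    }
                )
        bundle["effect_decomposition"] = decomp
    except Exception as exc:
        if config.outdir:
            out = Path(config.outdir)
            out.mkdir(parents=True, exist_ok=True)
            manifest["failed_stage"] = stage
            manifest["valid"] = False
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
            )
            (out / "partial_bundle.json").write_text(
                json.dumps(bundle, indent=2, sort_keys=True, default=float) + "\n",
                encoding="utf-8",
            )
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    manifest["valid"] = True
    bundle["manifest"] = manifest
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report_bundle.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=float) + "\n",
            encoding="utf-8",
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        render_tables(pd.DataFrame(bundle["per_allele_bmi_models"]), "csv",
                      out / "per_allele_bmi_models.csv")
        render_tables(pd.DataFrame(bundle["effect_decomposition"]), "csv",
                      out / "effect_decomposition.csv")
        (out / "flow_ledger.txt").write_text(qc.ledger.to_text() + "\n", encoding="utf-8")
    return bundle


def render_tables(results, fmt: str, path) -> None:
    """Write a result table as csv (missing = empty), json (missing = null)
    or fixed-width text (lines <= 120 characters)."""
    df = pd.DataFrame(results)
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False, na_rep="")
    elif fmt == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    elif fmt == "text":
        if df.empty:
            path.write_text(" ".join(df.columns) + "\n", encoding="utf-8")
            return
        s = df.to_string(index=False, na_rep="", line_width=120, float_format=lambda v: f"{v:.4g}")
        s = "\n".join(line[:120] for line in s.splitlines())
        path.write_text(s + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")
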