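"""Weight-history cleaning, BMI derivation and exclusion-flow accounting.

Self-reported body weights arrive in whole pounds or kilograms; cleaning
converts everything to whole kilograms, screens for lb/kg unit confusion
against a reference weight, derives BMI (kg/m^2) from baseline measured
height, rejects biologically implausible BMIs (< 16 or > 70), and applies an
ordered person-level exclusion cascade whose arithmetic is tracked in a
:class:`FlowLedger` (every step satisfies n_after = n_before - n_excluded and
a person counts only in the earliest rule that excludes them).
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
    "QCRuleSet",
    "FlowStep",
    "FlowLedger",
    "WeightError",
    "standardize_weight",
    "detect_unit_confusion",
    "compute_bmi",
    "correct_unit_confusion",
    "derive_bmi_columns",
    "build_flow_ledger",
    "run_qc",
    "QCResult",
]

RECALL_WEIGHT_COLS = ["weight_at_21", "weight_at_45", "weight_at_65"]
BASELINE_WEIGHT_COLS = ["measured_weight_kg", "self_weight_exam"]


class WeightError(ValueError):
    """A weight value violates a cleaning rule; carries the rule tag."""

    def __init__(self, message: str, rule: str):
        super().__init__(message)
        self.rule = rule


@dataclass(frozen=True)
class QCRuleSet:
    """Thresholds and constants of the cleaning rules."""

    bmi_lower: float = 16.0
    bmi_upper: float = 70.0
    min_diagnosis_age: float = 22.0
    lb_per_kg: float = 2.2046
    unit_confusion_rel_tol: float = 0.05
    height_min_cm: float = 100.0
    height_max_cm: float = 220.0

    def __post_init__(self) -> None:
        if not self.bmi_lower < self.bmi_upper:
            raise ValueError("bmi_lower must be below bmi_upper")
        if not 0.0 < self.unit_confusion_rel_tol < 1.0:
            raise ValueError("unit_confusion_rel_tol must be in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def standardize_weight(value: float, unit: str, ruleset: QCRuleSet = QCRuleSet()) -> int:
    """Convert a reported weight to whole kilograms.

    Pounds are divided by ``lb_per_kg`` (2.2046); the result is rounded
    half-away-from-zero to the whole unit, eliminating unit-of-report
    measurement error.
    """
    if unit not in ("lb", "kg"):
        raise WeightError(f"unknown weight unit {unit!r}", rule="unit")
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise WeightError(f"non-numeric weight {value!r}", rule="non_numeric") from None
    if not math.isfinite(v) or v <= 0:
        raise WeightError(f"non-positive weight {value!r}", rule="non_positive")
    kg = v / ruleset.lb_per_kg if unit == "lb" else v
    return _round_half_away(kg)


def detect_unit_confusion(
    self_weight: float,
    reference_weight: float,
    ruleset: QCRuleSet = QCRuleSet(),
) -> tuple[float, bool]:
    """Screen one self-reported weight for lb-entered-as-kg confusion.

    If the ratio of self-report to reference lies within
    ``unit_confusion_rel_tol`` of the lb/kg factor, the value is recoded as
    pounds (converted and rounded to whole kg) and flagged. A missing
    reference passes the value through unflagged: without a concurrent or
    trajectory reference there is no evidence to act on.
    """
    if self_weight is None or (isinstance(self_weight, float) and math.isnan(self_weight)):
        return (self_weight, False)
    if reference_weight is None or (
        isinstance(reference_weight, float) and math.isnan(reference_weight)
    ) or reference_weight <= 0:
        return (float(self_weight), False)
    ratio = float(self_weight) / float(reference_weight)
    if abs(ratio / ruleset.lb_per_kg - 1.0) <= ruleset.unit_confusion_rel_tol:
        return (float(standardize_weight(self_weight, "lb", ruleset)), True)
    return (float(self_weight), False)


def compute_bmi(
    weight_kg: float,
    height_cm: float,
    ruleset: QCRuleSet = QCRuleSet(),
) -> tuple[float, str]:
    """BMI = weight / (height/100)^2, with bound screening.

    Returns ``(value, status)``; out-of-bound BMIs are *rejected* (value set
    to NaN, status ``rejected_low``/``rejected_high``), never clipped. A
    missing operand yields ``(nan, 'missing')``; an implausible height yields
    ``(nan, 'invalid_height')``.
    """
    w = np.nan if weight_kg is None else float(weight_kg)
    h = np.nan if height_cm is None else float(height_cm)
    if math.isnan(w) or math.isnan(h):
        return (float("nan"), "missing")
    if not ruleset.height_min_cm <= h <= ruleset.height_max_cm:
        return (float("nan"), "invalid_height")
    bmi = w / (h / 100.0) ** 2
    if bmi < ruleset.bmi_lower:
        return (float("nan"), "rejected_low")
    if bmi > ruleset.bmi_upper:
        return (float("nan"), "rejected_high")
    return (bmi, "ok")


def correct_unit_confusion(
    cohort: pd.DataFrame, ruleset: QCRuleSet = QCRuleSet()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every self-reported weight column of a cohort.

    The reference for the examination self-report is the concurrent measured
    weight; for each recalled weight it is the median of the person's other
    weights (measured plus the remaining recalls). Returns the corrected
    cohort and a flag log (id, column, original, corrected).
    """
    df = cohort.copy()
    flags: list[tuple[str, str, float, float]] = []
    measured = pd.to_numeric(df.get("measured_weight_kg", np.nan)).to_numpy(dtype=float)
    cols = [c for c in ["self_weight_exam", *RECALL_WEIGHT_COLS] if c in df.columns]
    vals = {c: pd.to_numeric(df[c]).to_numpy(dtype=float) for c in cols}
    for col in cols:
        v = vals[col]
        out = v.copy()
        for i in np.flatnonzero(~np.isnan(v)):
            if col == "self_weight_exam":
                ref = measured[i]
            else:
                others = [measured[i]] + [
                    vals[c][i] for c in cols if c not in (col, "self_weight_exam")
                ]
                others = [x for x in others if not math.isnan(x)]
                ref = float(np.median(others)) if others else float("nan")
            corrected, flagged = detect_unit_confusion(v[i], ref, ruleset)
            if flagged:
                out[i] = corrected
                flags.append((df["id"].iloc[i], col, float(v[i]), corrected))
        df[col] = out
    log = pd.DataFrame(flags, columns=["id", "column", "original", "corrected"])
    return df, log


def derive_bmi_columns(
    cohort: pd.DataFrame,
    ruleset: QCRuleSet = QCRuleSet(),
    apply_bounds: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add BMI columns from weights and baseline measured height.

    Produces ``bmi_measured``, ``bmi_self_exam`` and ``bmi_at_21/45/65``.
    With ``apply_bounds`` BMIs outside the plausibility window are dropped
    (set missing) and logged; the person is retained.
    """
    df = cohort.copy()
    h = pd.to_numeric(df["height_cm"]).to_numpy(dtype=float)
    h2 = (h / 100.0) ** 2
    bad_h = np.isnan(h) | (h < ruleset.height_min_cm) | (h > ruleset.height_max_cm)
    rejections: list[tuple[str, str, float, str]] = []
    mapping = {
        "bmi_measured": "measured_weight_kg",
        "bmi_self_exam": "self_weight_exam",
        "bmi_at_21": "weight_at_21",
        "bmi_at_45": "weight_at_45",
        "bmi_at_65": "weight_at_65",
    }
    for bcol, wcol in mapping.items():
        if wcol not in df.columns:
            continue
        w = pd.to_numeric(df[wcol]).to_numpy(dtype=float)
        bmi = w / h2
        bmi[bad_h] = np.nan
        if apply_bounds:
            low = bmi < ruleset.bmi_lower
            high = bmi > ruleset.bmi_upper
            for i in np.flatnonzero(low | high):
                status = "rejected_low" if low[i] else "rejected_high"
                rejections.append((df["id"].iloc[i], bcol, float(bmi[i]), status))
            bmi[low | high] = np.nan
        df[bcol] = bmi
    log = pd.DataFrame(rejections, columns=["id", "column", "bmi", "status"])
    return df, log


# --- flow ledger -------------------------------------------------------------

@dataclass
class FlowStep:
    rule: str
    n_before: int
    n_excluded: int
    n_after: int


@dataclass
class FlowLedger:
    """Ordered exclusion accounting for the analytic-sample flowchart."""

    initial_n: int
    steps: list[FlowStep] = field(default_factory=list)
    excluded_ids: dict[str, list] = field(default_factory=dict)

    @property
    def final_n(self) -> int:
        return self.steps[-1].n_after if self.steps else self.initial_n

    def add(self, rule: str, excluded: list) -> None:
        before = self.final_n
        self.steps.append(FlowStep(rule, before, len(excluded), before - len(excluded)))
        self.excluded_ids[rule] = list(excluded)

    def validate(self) -> None:
        prev = self.initial_n
        total = 0
        for s in self.steps:
            if s.n_before != prev:
                raise ValueError(f"step {s.rule}: n_before {s.n_before} != previous n_after {prev}")
            if s.n_after != s.n_before - s.n_excluded:
                raise ValueError(f"step {s.rule}: n_after arithmetic violated")
            prev = s.n_after
            total += s.n_excluded
        if self.final_n + total != self.initial_n:
            raise ValueError("ledger does not conserve persons")

    @classmethod
    def from_counts(cls, initial_n: int, counts: list[tuple[str, int]]) -> "FlowLedger":
        """Build a ledger from printed per-rule exclusion counts."""
        led = cls(initial_n)
        n = initial_n
        for rule, k in counts:
            led.steps.append(FlowStep(rule, n, k, n - k))
            n -= k
        led.validate()
        return led

    def to_json(self, path=None) -> str:
        d = {
            "initial_n": self.initial_n,
            "final_n": self.final_n,
            "steps": [dataclasses.asdict(s) for s in self.steps],
        }
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s + "\n")
        return s

    def to_text(self) -> str:
        lines = [f"{'rule':<32}{'before':>9}{'excluded':>10}{'after':>9}"]
        for s in self.steps:
            lines.append(f"{s.rule:<32}{s.n_before:>9}{s.n_excluded:>10}{s.n_after:>9}")
        lines.append(f"final analytic n = {self.final_n}")
        return "\n".join(lines)


def _n_weight_measurements(df: pd.DataFrame) -> pd.Series:
    cols = [c for c in BASELINE_WEIGHT_COLS + RECALL_WEIGHT_COLS if c in df.columns]
    return df[cols].notna().sum(axis=1)


def build_flow_ledger(
    cohort: pd.DataFrame,
    ruleset: QCRuleSet = QCRuleSet(),
    kinship: pd.DataFrame | None = None,
) -> FlowLedger:
    """Apply the ordered person-level exclusion cascade and account for it.

    Rule order: pregnancy/amputation (persons left with no recalled weight
    once their baseline measures are removed), diabetes diagnosis before the
    minimum plausible type-2 age, no usable height or self-reported weight,
    missing genetic-analysis group, missing education, then kinship-based
    relatedness pruning. Overlapping claims resolve first-rule-wins because
    rules are applied sequentially to the remaining sample.
    """
    from .genetics import prune_relatives  # local import avoids cycle at import time

    df = cohort.copy()
    led = FlowLedger(initial_n=len(df))

    preg = pd.to_numeric(df.get("pregnant", 0)).fillna(0).astype(int) == 1
    amp = pd.to_numeric(df.get("amputation", 0)).fillna(0).astype(int) == 1
    recalled = df[[c for c in RECALL_WEIGHT_COLS if c in df.columns]]
    no_recall = recalled.isna().all(axis=1) if len(recalled.columns) else pd.Series(True, index=df.index)
    mask = (preg | amp) & no_recall
    led.add("pregnancy_amputation", df.loc[mask, "id"].tolist())
    df = df[~mask]

    dx = pd.to_numeric(df.get("diabetes_diagnosis_age", np.nan))
    mask = dx < ruleset.min_diagnosis_age
    led.add("early_diabetes_diagnosis", df.loc[mask, "id"].tolist())
    df = df[~mask]

    h = pd.to_numeric(df["height_cm"])
    bad_h = h.isna() | (h < ruleset.height_min_cm) | (h > ruleset.height_max_cm)
    usable_cols = [c for c in ("bmi_at_21", "bmi_at_45", "bmi_at_65") if c in df.columns]
    if not usable_cols:
        usable_cols = [c for c in RECALL_WEIGHT_COLS if c in df.columns]
    no_weight = df[usable_cols].isna().all(axis=1)
    mask = bad_h | no_weight
    led.add("no_usable_height_or_weight", df.loc[mask, "id"].tolist())
    df = df[~mask]

    mask = df["analysis_group"].isna() | (df["analysis_group"].astype(str).str.strip() == "")
    led.add("missing_analysis_group", df.loc[mask, "id"].tolist())
    df = df[~mask]

    mask = pd.to_numeric(df["education"]).isna()
    led.add("missing_education", df.loc[mask, "id"].tolist())
    df = df[~mask]

    if kinship is not None and len(kinship):
        ids = set(df["id"])
        pairs = kinship[kinship["id1"].isin(ids) & kinship["id2"].isin(ids)]
        n_weights = dict(zip(df["id"], _n_weight_measurements(df)))
        keep = prune_relatives(
            list(pairs[["id1", "id2", "pi_hat"]].itertuples(index=False, name=None)),
            n_weights,
        )
        mask = ~df["id"].isin(keep)
        led.add("relatedness", df.loc[mask, "id"].tolist())
        df = df[~mask]
    else:
        led.add("relatedness", [])

    led.validate()
    return led


class QCResult(NamedTuple):
    cohort: pd.DataFrame           # analytic sample (exclusions applied)
    cohort_full: pd.DataFrame      # cleaned full cohort with 'analytic' flag;
                                   # variance calculations keep every record
    ledger: FlowLedger
    unit_flags: pd.DataFrame
    bmi_rejections: pd.DataFrame


def run_qc(
    cohort: pd.DataFrame,
    kinship: pd.DataFrame | None = None,
    ruleset: QCRuleSet = QCRuleSet(),
) -> QCResult:
    """Full cleaning pass: unit screening, measure removal, BMI derivation,
    exclusion cascade. Returns the analytic cohort plus the accounting."""
    df, unit_flags = correct_unit_confusion(cohort, ruleset)
    # pregnancy/amputation invalidate the baseline anthropometry only;
    # recalled weights were reported for non-pregnant times and are retained
    preg_amp = (
        (pd.to_numeric(df.get("pregnant", 0)).fillna(0).astype(int) == 1)
        | (pd.to_numeric(df.get("amputation", 0)).fillna(0).astype(int) == 1)
    )
    for col in BASELINE_WEIGHT_COLS:
        if col in df.columns:
            df.loc[preg_amp, col] = np.nan
    df, rejections = derive_bmi_columns(df, ruleset)
    ledger = build_flow_ledger(df, ruleset, kinship)
    keep_ids = set(df["id"])
    for ids in ledger.excluded_ids.values():
        keep_ids -= set(ids)
    df = df.reset_index(drop=True)
    df["analytic"] = df["id"].isin(keep_ids)
    out = df[df["analytic"]].reset_index(drop=True)
    return QCResult(out, df, ledger, unit_flags, rejections)
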