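"""American Diabetes Association glycemic classification at examination.

Type 2 diabetes at exam is called when any criterion is met: fasting glucose
>= 126 mg/dL, 2-h post-load (OGTT) glucose >= 200 mg/dL, HbA1c >= 6.5%, or
current diabetes medication. Impaired fasting glucose is defined only among
non-diabetics (fasting 100–125 mg/dL or post-load 140–199 mg/dL); controlled
diabetes only among diabetics (HbA1c < 7%). HOMA indices use the standard
Matthews formulas — HOMA-IR = glucose*insulin/405 and
HOMA-B = 360*insulin/(glucose - 63) with glucose in mg/dL and insulin in
mU/L — since these derived indices have a single conventional form; the
constants are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ADAThresholds", "ADAClassification", "classify_glycemia", "classify_glycemia_frame"]


@dataclass(frozen=True)
class ADAThresholds:
    fasting_t2d: float = 126.0
    ogtt_t2d: float = 200.0
    hba1c_t2d: float = 6.5
    hba1c_controlled: float = 7.0
    ifg_fasting: tuple[float, float] = (100.0, 125.0)
    ifg_ogtt: tuple[float, float] = (140.0, 199.0)
    homa_ir_denom: float = 405.0
    homa_b_num: float = 360.0
    homa_b_offset: float = 63.0


@dataclass
class ADAClassification:
    t2d_at_exam: bool
    impaired_fasting_glucose: bool | None   # defined only when not diabetic
    controlled: bool | None                 # defined only when diabetic
    homa_ir: float
    homa_b: float


def _num(x) -> float:
    if x is None:
        return float("nan")
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def classify_glycemia(record, thresholds: ADAThresholds = ADAThresholds()) -> ADAClassification:
    """Classify one participant record (mapping or Series) at examination."""
    fg = _num(record.get("fasting_glucose"))
    ogtt = _num(record.get("ogtt_glucose"))
    a1c = _num(record.get("hba1c_pct"))
    ins = _num(record.get("fasting_insulin"))
    meds = _num(record.get("on_diabetes_meds"))
    if all(math.isnan(v) for v in (fg, ogtt, a1c)) and math.isnan(meds):
        raise ValueError("no glycemic measurement present; classification undefined")
    t = thresholds
    t2d = (
        (not math.isnan(fg) and fg >= t.fasting_t2d)
        or (not math.isnan(ogtt) and ogtt >= t.ogtt_t2d)
        or (not math.isnan(a1c) and a1c >= t.hba1c_t2d)
        or (not math.isnan(meds) and meds >= 1)
    )
    ifg: bool | None = None
    if not t2d:
        ifg = (
            (not math.isnan(fg) and t.ifg_fasting[0] <= fg <= t.ifg_fasting[1])
            or (not math.isnan(ogtt) and t.ifg_ogtt[0] <= ogtt <= t.ifg_ogtt[1])
        )
    controlled: bool | None = None
    if t2d and not math.isnan(a1c):
        controlled = a1c < t.hba1c_controlled
    homa_ir = fg * ins / t.homa_ir_denom if not (math.isnan(fg) or math.isnan(ins)) else float("nan")
    if math.isnan(fg) or math.isnan(ins) or fg <= t.homa_b_offset:
        homa_b = float("nan")  # denominator non-positive: index undefined
    else:
        homa_b = t.homa_b_num * ins / (fg - t.homa_b_offset)
    return ADAClassification(bool(t2d), ifg, controlled, homa_ir, homa_b)


def classify_glycemia_frame(
    df: pd.DataFrame, thresholds: ADAThresholds = ADAThresholds()
) -> pd.DataFrame:
    """Vectorized classification; returns one column per classification field.

    Adds ``diabetic_before_or_at_exam`` combining the exam call with a
    reported prior diagnosis, the grouping used for descriptive stratification.
    """
    t = thresholds
    fg = pd.to_numeric(df["fasting_glucose"]).to_numpy(dtype=float)
    ogtt = pd.to_numeric(df.get("ogtt_glucose", np.nan)).to_numpy(dtype=float)
    a1c = pd.to_numeric(df.get("hba1c_pct", np.nan)).to_numpy(dtype=float)
    ins = pd.to_numeric(df.get("fasting_insulin", np.nan)).to_numpy(dtype=float)
    meds = pd.to_numeric(df.get("on_diabetes_meds", 0)).fillna(0).to_numpy(dtype=float)
    t2d = (
        (fg >= t.fasting_t2d)
        | (ogtt >= t.ogtt_t2d)
        | (a1c >= t.hba1c_t2d)
        | (meds >= 1)
    )
    ifg = np.where(
        t2d,
        np.nan,
        (
            ((fg >= t.ifg_fasting[0]) & (fg <= t.ifg_fasting[1]))
            | ((ogtt >= t.ifg_ogtt[0]) & (ogtt <= t.ifg_ogtt[1]))
        ).astype(float),
    )
    controlled = np.where(t2d & ~np.isnan(a1c), (a1c < t.hba1c_controlled).astype(float), np.nan)
    homa_ir = fg * ins / t.homa_ir_denom
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_b = np.where(fg > t.homa_b_offset, t.homa_b_num * ins / (fg - t.homa_b_offset), np.nan)
    dx = pd.to_numeric(df.get("diabetes_diagnosis_age", np.nan)).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "t2d_at_exam": t2d,
            "impaired_fasting_glucose": ifg,
            "controlled": controlled,
            "homa_ir": homa_ir,
            "homa_b": homa_b,
            "diabetic_before_or_at_exam": t2d | ~np.isnan(dx),
        },
        index=df.index,
    )
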