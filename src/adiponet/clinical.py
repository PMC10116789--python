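"""Closed-form clinical indices used in obesity / bariatric-surgery cohorts.

All inputs are on the units conventional in European clinical chemistry
(glucose and lipids in mmol/L, insulin either pmol/L or mIU/L, weight in kg).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "homa_ir",
    "insulin_pmol_to_miu",
    "friedewald_ldl",
    "percent_excess_weight_loss",
    "derive_clinical_columns",
    "FRIEDEWALD_TG_LIMIT",
    "INSULIN_PMOL_PER_MIU",
]

#: pmol/L of insulin per mIU/L (standard clinical conversion constant).
INSULIN_PMOL_PER_MIU = 6.945

#: Triglyceride bound (mmol/L) above which the Friedewald estimate is invalid.
FRIEDEWALD_TG_LIMIT = 4.5


def homa_ir(glucose: float, insulin_miu: float) -> float:
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = fasting glucose (mmol/L) × fasting insulin (mIU/L) / 22.5.

    Parameters
    ----------
    glucose : float
        Fasting glucose in mmol/L, non-negative.
    insulin_miu : float
        Fasting insulin in mIU/L, non-negative.
    """
    glucose = float(glucose)
    insulin_miu = float(insulin_miu)
    if glucose < 0 or insulin_miu < 0:
        raise ValueError("HOMA-IR inputs must be non-negative")
    return glucose * insulin_miu / 22.5


def insulin_pmol_to_miu(insulin_pmol: float) -> float:
    """Convert insulin from pmol/L to mIU/L (divide by 6.945)."""
    insulin_pmol = float(insulin_pmol)
    if insulin_pmol < 0:
        raise ValueError("insulin concentration must be non-negative")
    return insulin_pmol / INSULIN_PMOL_PER_MIU


def friedewald_ldl(total_cholesterol: float, hdl: float, tg: float) -> float:
    """Friedewald estimate of LDL cholesterol, all in mmol/L.

    LDL = TC − HDL − TG/2.2.  Invalid for TG > 4.5 mmol/L; a negative
    estimate is returned but flagged with a warning.
    """
    total_cholesterol = float(total_cholesterol)
    hdl = float(hdl)
    tg = float(tg)
    if min(total_cholesterol, hdl, tg) < 0:
        raise ValueError("lipid concentrations must be non-negative")
    if tg > FRIEDEWALD_TG_LIMIT:
        raise ValueError(
            f"Friedewald formula invalid for TG > {FRIEDEWALD_TG_LIMIT} mmol/L "
            f"(got {tg})"
        )
    ldl = total_cholesterol - hdl - tg / 2.2
    if ldl < 0:
        warnings.warn(
            f"Friedewald LDL estimate is negative ({ldl:.3f} mmol/L)",
            stacklevel=2,
        )
    return ldl


def percent_excess_weight_loss(
    weight_pre: float, weight_post: float, ideal_weight: float
) -> float:
    """Percent excess weight loss after bariatric surgery.

    %EWL = (pre − post) / (pre − ideal) × 100.  Requires pre-operative
    weight strictly above ideal body weight.
    """
    weight_pre = float(weight_pre)
    weight_post = float(weight_post)
    ideal_weight = float(ideal_weight)
    if weight_pre <= 0 or weight_post <= 0 or ideal_weight <= 0:
        raise ValueError("weights must be positive")
    if weight_pre <= ideal_weight:
        raise ValueError(
            "pre-operative weight must exceed ideal body weight "
            f"(pre={weight_pre}, ideal={ideal_weight})"
        )
    return (weight_pre - weight_post) / (weight_pre - ideal_weight) * 100.0


def derive_clinical_columns(clinical: pd.DataFrame) -> pd.DataFrame:
    """Append derived index columns to a clinical table.

    Adds, where the source columns are present:

    * ``insulin_miu``  from ``insulin_pmol``
    * ``homa_ir``      from ``glucose_mmol`` and insulin (mIU/L)
    * ``ldl_friedewald`` and ``ldl_flag`` (negative estimate) from
      ``total_cholesterol``/``hdl``/``tg``; rows with TG above the validity
      bound get NaN and flag ``tg_out_of_range``
    * ``pct_ewl``      from ``weight_pre``/``weight_post``/``ideal_weight``

    Returns a copy; the input frame is not modified.
    """
    out = clinical.copy()
    if "insulin_pmol" in out.columns and "insulin_miu" not in out.columns:
        out["insulin_miu"] = out["insulin_pmol"].astype(float) / INSULIN_PMOL_PER_MIU
    if "glucose_mmol" in out.columns and "insulin_miu" in out.columns:
        out["homa_ir"] = out["glucose_mmol"].astype(float) * out["insulin_miu"] / 22.5
    lipid_cols = {"total_cholesterol", "hdl", "tg"}
    if lipid_cols.issubset(out.columns):
        tc = out["total_cholesterol"].astype(float)
        hdl = out["hdl"].astype(float)
        tg = out["tg"].astype(float)
        ldl = tc - hdl - tg / 2.2
        invalid = tg > FRIEDEWALD_TG_LIMIT
        ldl = ldl.mask(invalid)
        out["ldl_friedewald"] = ldl
        flag = np.where(invalid, "tg_out_of_range", "")
        flag = np.where(~invalid & (ldl < 0), "negative_estimate", flag)
        out["ldl_flag"] = flag
    weight_cols = {"weight_pre", "weight_post", "ideal_weight"}
    if weight_cols.issubset(out.columns):
        pre = out["weight_pre"].astype(float)
        post = out["weight_post"].astype(float)
        ideal = out["ideal_weight"].astype(float)
        excess = pre - ideal
        out["pct_ewl"] = ((pre - post) / excess * 100.0).where(excess > 0)
    return out
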