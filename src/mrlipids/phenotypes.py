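"""Derivation of analysis variables from raw phenotype columns.

Everything here is deterministic arithmetic on a per-individual cohort
table: converting beverage counts to grams of ethanol per week, the
log exposure transform, drinker categorisation, the Friedewald LDL-c
formula, the HDL2-c subtraction, the isoform-insensitive Lp(a)
rescaling, and the log transforms applied to the skewed lipids.

Units are mg/dL throughout; alcohol is grams of ethanol per week.
Derived columns added to a cohort table carry a ``derived_`` prefix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# grams of ethanol per beverage unit (4 oz wine / 12 oz beer / 1.5 oz liquor)
GRAMS_PER_WINE = 10.8
GRAMS_PER_BEER = 13.2
GRAMS_PER_LIQUOR = 15.1

#: weekly grams above which a current drinker counts as heavy, by sex
HEAVY_THRESHOLD_G_WK = {"M": 210.0, "F": 105.0}

#: mg/dL of triglycerides above which Friedewald LDL-c is not computed
FRIEDEWALD_TG_LIMIT = 400.0

#: rescaling factor aligning the legacy Lp(a) assay with an
#: apo(a)-isoform-insensitive assay
LPA_CORRECTION_FACTOR = 1.326

#: lipids analysed on the natural-log scale (skewed distributions)
LOG_SCALE_LIPIDS = ("tg", "hdl", "hdl2", "sdldl", "apob", "lpa")

DRINKER_CATEGORIES = ("never", "former", "infrequent", "low_to_moderate", "heavy")
DRINKING_STATUSES = ("never", "former", "current")


@dataclass(frozen=True)
class BeverageIntake:
    """Weekly beverage counts (may be fractional)."""

    wine_4oz_per_wk: float = 0.0
    beer_12oz_per_wk: float = 0.0
    liquor_1_5oz_per_wk: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.wine_4oz_per_wk, self.beer_12oz_per_wk, self.liquor_1_5oz_per_wk):
            if f < 0:
                raise ValueError("beverage counts must be non-negative")

    @property
    def drinks_per_wk(self) -> float:
        return self.wine_4oz_per_wk + self.beer_12oz_per_wk + self.liquor_1_5oz_per_wk


def drinks_to_grams(intake: BeverageIntake) -> float:
    """Ethanol grams/week from weekly wine, beer and liquor counts."""
    return (
        GRAMS_PER_WINE * intake.wine_4oz_per_wk
        + GRAMS_PER_BEER * intake.beer_12oz_per_wk
        + GRAMS_PER_LIQUOR * intake.liquor_1_5oz_per_wk
    )


def log_alcohol(g_wk):
    """ln(g/wk + 1), the analysis scale for alcohol consumption.

    Accepts scalars or arrays; negative input is rejected.
    """
    arr = np.asarray(g_wk, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("alcohol g/wk must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(g_wk) else out


def classify_drinker(status: str, g_wk: float, sex: str, drinks_per_wk: float) -> str:
    """Assign the five-level drinker category.

    Never/former pass through.  Current drinkers with less than one
    drink per week are *infrequent* (their consumption is recorded as
    0 g/wk).  Otherwise the sex-specific weekly-gram threshold splits
    low-to-moderate (inclusive at the boundary) from heavy (strict >).
    """
    if status not in DRINKING_STATUSES:
        raise ValueError(f"unknown drinking status {status!r}")
    if status in ("never", "former"):
        return status
    if sex not in HEAVY_THRESHOLD_G_WK:
        raise ValueError(f"unknown sex {sex!r}")
    if drinks_per_wk < 1:
        return "infrequent"
    return "heavy" if g_wk > HEAVY_THRESHOLD_G_WK[sex] else "low_to_moderate"


def recorded_g_wk(status: str, g_wk: float, drinks_per_wk: float) -> float:
    """Consumption as analysed: 0 for never/former and for current
    drinkers under one drink per week."""
    if status != "current" or drinks_per_wk < 1:
        return 0.0
    return float(g_wk)


def friedewald_ldl(tc, hdl, tg):
    """LDL-c = TC − HDL-c − TG/5 (mg/dL); undefined when TG > 400 mg/dL.

    Missing (NaN) parents propagate to a missing result.
    """
    tc, hdl, tg = (float("nan") if v is None else float(v) for v in (tc, hdl, tg))
    for v in (tc, hdl, tg):
        if not math.isnan(v) and v < 0:
            raise ValueError("lipid inputs must be non-negative")
    if math.isnan(tc) or math.isnan(hdl) or math.isnan(tg) or tg > FRIEDEWALD_TG_LIMIT:
        return float("nan")
    return tc - hdl - tg / 5.0


def correct_lpa(lpa_raw):
    """Rescale a legacy Lp(a) assay value by 1.326; NaN propagates."""
    if lpa_raw is None:
        return float("nan")
    v = float(lpa_raw)
    if math.isnan(v):
        return v
    if v < 0:
        raise ValueError("Lp(a) must be non-negative")
    return LPA_CORRECTION_FACTOR * v


def percent_change(beta_log: float) -> float:
    """Reporting transform for a log-scale coefficient: 100·(e^β − 1)."""
    return 100.0 * (math.exp(beta_log) - 1.0)


def _safe_log(series: pd.Series, name: str) -> pd.Series:
    bad = series.notna() & (series <= 0)
    if bad.any():
        logger.warning(
            "%d non-positive %s values set to missing before log transform",
            int(bad.sum()), name,
        )
    masked = series.where(~bad)
    return np.log(masked)


def derive_panel(raw: pd.DataFrame) -> pd.DataFrame:
    """Vectorised lipid-panel derivation for a raw cohort table.

    Expects columns ``tg, total_chol, hdl, hdl3, lpa, sdldl, apob``
    (missing allowed per cell) and returns the derived columns:
    ``hdl2`` (HDL-c − HDL3-c), ``ldl`` (Friedewald, missing when
    TG > 400), ``lpa_corrected`` and the six ``ln_*`` companions.
    Non-positive values hitting a log transform become missing.
    """
    out = pd.DataFrame(index=raw.index)
    out["hdl2"] = raw["hdl"] - raw["hdl3"]
    ldl = raw["total_chol"] - raw["hdl"] - raw["tg"] / 5.0
    out["ldl"] = ldl.where(raw["tg"] <= FRIEDEWALD_TG_LIMIT)
    out["lpa_corrected"] = raw["lpa"] * LPA_CORRECTION_FACTOR
    log_sources = {
        "tg": raw["tg"],
        "hdl": raw["hdl"],
        "hdl2": out["hdl2"],
        "sdldl": raw["sdldl"],
        "apob": raw["apob"],
        "lpa": out["lpa_corrected"],
    }
    for name, series in log_sources.items():
        out[f"ln_{name}"] = _safe_log(series, name)
    return out


def derive_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append all ``derived_`` analysis columns to a raw cohort table.

    Adds the recorded exposure (grams/week and ln(g/wk+1)), the
    five-level drinker category, and the derived lipid panel.  The
    input frame is not mutated.
    """
    df = cohort.copy()
    rec = np.where(
        (df["drinking_status"] == "current") & (df["drinks_per_wk"] >= 1),
        df["alcohol_g_wk"], 0.0,
    )
    df["derived_g_wk_recorded"] = rec
    df["derived_log_alcohol"] = log_alcohol(rec)
    df["derived_category"] = [
        classify_drinker(s, g, x, d)
        for s, g, x, d in zip(
            df["drinking_status"], df["alcohol_g_wk"], df["sex"], df["drinks_per_wk"]
        )
    ]
    panel = derive_panel(df)
    for col in panel.columns:
        df[f"derived_{col}"] = panel[col]
    return df


COLUMN_DICTIONARY = {
    "derived_g_wk_recorded": "alcohol g/wk as analysed (0 if not a current drinker of >=1 drink/wk)",
    "derived_log_alcohol": "ln(recorded g/wk + 1)",
    "derived_category": "never/former/infrequent/low_to_moderate/heavy",
    "derived_hdl2": "HDL2-c = HDL-c - HDL3-c (mg/dL)",
    "derived_ldl": "Friedewald LDL-c (mg/dL), missing when TG > 400",
    "derived_lpa_corrected": "Lp(a) x 1.326 (mg/dL)",
    "derived_ln_tg": "ln TG",
    "derived_ln_hdl": "ln HDL-c",
    "derived_ln_hdl2": "ln HDL2-c",
    "derived_ln_sdldl": "ln sdLDL-c",
    "derived_ln_apob": "ln apoB",
    "derived_ln_lpa": "ln corrected Lp(a)",
}
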