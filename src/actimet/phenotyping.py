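"""Metabolic/BMI phenotype classification and covariate construction.

Participants are grouped by BMI band (normal weight 18.5 to <25,
overweight 25 to <30, obese >=30; underweight <18.5 excluded) and labelled
metabolically *healthy* when they carry fewer than 2 of 5 risk factors:

* HDL cholesterol < 1.03 mmol/L (men) / < 1.29 mmol/L (women), or
  lipid-lowering medication;
* blood pressure >= 130/85 mm Hg (SBP >= 130 OR DBP >= 85), or
  antihypertensive medication;
* fasting plasma glucose >= 5.6 mmol/L, or diabetic medication;
* triglycerides >= 1.7 mmol/L;
* HOMA-IR > 5.12 (strict).

The cross of the two axes gives the six phenotypes used by the analysis,
with healthy normal weight as the reference. Covariate helpers build the
0–6 diet score, the sex-specific alcohol categories, and carry back
prior-wave values when the current wave is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HDL_CUTOFF = {"male": 1.03, "female": 1.29}
SBP_CUTOFF = 130.0
DBP_CUTOFF = 85.0
GLUCOSE_CUTOFF = 5.6
TG_CUTOFF = 1.7
HOMA_IR_CUTOFF = 5.12

RISK_FACTORS = ("low_hdl", "hypertension", "high_glucose",
                "high_triglycerides", "insulin_resistance")

BMI_BANDS = (("underweight", 0.0, 18.5), ("normal", 18.5, 25.0),
             ("overweight", 25.0, 30.0), ("obese", 30.0, math.inf))

#: the six analysis groups, reference first
PHENOTYPE_LEVELS = (
    "healthy_normal",
    "unhealthy_normal",
    "healthy_overweight",
    "unhealthy_overweight",
    "healthy_obese",
    "unhealthy_obese",
)


class PhenotypingError(ValueError):
    pass


class MissingDataError(PhenotypingError):
    """A required field is missing for a participant (complete-case drop)."""


@dataclass(frozen=True)
class PhenotypeLabel:
    bmi_category: str
    metabolically_healthy: bool
    group: str
    risk_factor_count: int

    def __post_init__(self) -> None:
        if self.metabolically_healthy != (self.risk_factor_count < 2):
            raise PhenotypingError("healthy flag inconsistent with risk count")


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value == ""


def bmi_category(bmi: float) -> str:
    """WHO BMI band; 'underweight' marks exclusion from the analysis."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise PhenotypingError(f"BMI must be positive and finite, got {bmi!r}")
    for name, lo, hi in BMI_BANDS:
        if lo <= bmi < hi:
            return name
    raise PhenotypingError(f"unclassifiable BMI {bmi!r}")  # pragma: no cover


def count_risk_factors(rec: Mapping[str, Any]) -> tuple[int, dict[str, bool]]:
    """Count the five risk-factor flags from a participant record.

    ``rec`` must provide sex, hdl, lipid_meds, sbp, dbp, bp_meds,
    fasting_glucose, diabetes_meds, triglycerides and homa_ir. Any missing
    factor input raises :class:`MissingDataError` (complete-case analysis).
    """
    required = ("sex", "hdl", "lipid_meds", "sbp", "dbp", "bp_meds",
                "fasting_glucose", "diabetes_meds", "triglycerides", "homa_ir")
    missing = [k for k in required if k not in rec or _is_missing(rec[k])]
    if missing:
        raise MissingDataError(f"missing risk-factor inputs: {missing}")
    sex = str(rec["sex"]).lower()
    if sex not in HDL_CUTOFF:
        raise PhenotypingError(f"sex must be 'male' or 'female', got {rec['sex']!r}")
    flags = {
        "low_hdl": rec["hdl"] < HDL_CUTOFF[sex] or bool(rec["lipid_meds"]),
        "hypertension": rec["sbp"] >= SBP_CUTOFF or rec["dbp"] >= DBP_CUTOFF
                        or bool(rec["bp_meds"]),
        "high_glucose": rec["fasting_glucose"] >= GLUCOSE_CUTOFF
                        or bool(rec["diabetes_meds"]),
        "high_triglycerides": rec["triglycerides"] >= TG_CUTOFF,
        "insulin_resistance": rec["homa_ir"] > HOMA_IR_CUTOFF,  # strict >
    }
    return sum(flags.values()), flags


def classify_phenotype(rec: Mapping[str, Any]) -> PhenotypeLabel:
    """Six-level metabolic/BMI phenotype for one participant record."""
    cat = bmi_category(rec["bmi"])
    if cat == "underweight":
        raise PhenotypingError("underweight participants are excluded")
    count, _ = count_risk_factors(rec)
    healthy = count < 2
    group = f"{'healthy' if healthy else 'unhealthy'}_{cat}"
    return PhenotypeLabel(cat, healthy, group, count)


def diet_score(fruit_veg: str, milk: str, bread: str) -> tuple[int, str]:
    """0–6 diet score from three components, and its category.

    Components are each coded 0/1/2 (fruit & veg: less than daily / daily /
    twice or more; milk: whole / semi-skimmed / skimmed or other; bread:
    white / mixed or none / wholemeal or brown). 0–2 unhealthy, 3–4
    moderately healthy, 5–6 healthy.
    """
    codings = {
        "fruit_veg": {"less_than_daily": 0, "daily": 1, "twice_or_more": 2},
        "milk": {"whole": 0, "semi_skimmed": 1, "skimmed_or_other": 2},
        "bread": {"white": 0, "mixed_or_none": 1, "wholemeal_or_brown": 2},
    }
    score = 0
    for name, value in (("fruit_veg", fruit_veg), ("milk", milk), ("bread", bread)):
        try:
            score += codings[name][value]
        except KeyError:
            raise PhenotypingError(f"unknown {name} category {value!r}") from None
    category = "unhealthy" if score <= 2 else "moderate" if score <= 4 else "healthy"
    return score, category


def alcohol_category(units_per_week: float, sex: str) -> str:
    """Abstainer (0), moderate (1–14 women / 1–21 men), or high."""
    if units_per_week < 0:
        raise PhenotypingError("alcohol units must be nonnegative")
    if units_per_week == 0:
        return "abstainer"
    limit = 14.0 if str(sex).lower() == "female" else 21.0
    return "moderate" if units_per_week <= limit else "high"


def carry_back(current: Any, prior: Any) -> tuple[Any, str]:
    """Use the current-wave value, falling back to the prior wave.

    Returns ``(value, provenance)`` with provenance 'current' or 'prior';
    raises :class:`MissingDataError` when both waves are missing.
    """
    if not _is_missing(current):
        return current, "current"
    if not _is_missing(prior):
        return prior, "prior"
    raise MissingDataError("value missing at both waves")


def phenotype_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a cohort table; complete-case after carry-back.

    Adds ``bmi_cat, rf_count, healthy, phenotype6, diet_score, diet_cat,
    alcohol_cat`` plus resolved covariates. Returns ``(kept, excluded)``
    where ``excluded`` lists participant ids with the exclusion reason.
    """
    kept_rows: list[dict] = []
    excluded: list[dict] = []
    for _, row in df.iterrows():
        rec = row.to_dict()
        pid = rec.get("participant_id", "?")
        try:
            for col in ("occ_position", "smoking"):
                prior = rec.get(f"{col}_prior")
                if col in rec:
                    rec[col], rec[f"{col}_source"] = carry_back(rec[col], prior)
            cat = bmi_category(rec["bmi"])
            if cat == "underweight":
                raise PhenotypingError("underweight (BMI < 18.5)")
            label = classify_phenotype(rec)
            rec["bmi_cat"] = label.bmi_category
            rec["rf_count"] = label.risk_factor_count
            rec["healthy"] = label.metabolically_healthy
            rec["phenotype6"] = label.group
            _, flags = count_risk_factors(rec)
            for name, flag in flags.items():
                rec[f"rf_{name}"] = flag
            rec["diet_score"], rec["diet_cat"] = diet_score(
                rec["fruit_veg"], rec["milk"], rec["bread"])
            rec["alcohol_cat"] = alcohol_category(rec["alcohol_units"], rec["sex"])
        except PhenotypingError as err:
            excluded.append({"participant_id": pid, "reason": str(err)})
            continue
        kept_rows.append(rec)
    if excluded:
        logger.info("phenotyping excluded %d of %d participants",
                    len(excluded), len(df))
    kept = pd.DataFrame(kept_rows)
    if len(kept):
        kept["phenotype6"] = pd.Categorical(kept["phenotype6"],
                                            categories=PHENOTYPE_LEVELS)
    return kept, pd.DataFrame(excluded, columns=["participant_id", "reason"])
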