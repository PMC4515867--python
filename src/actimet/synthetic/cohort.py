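"""Synthetic cohort tables with latent ground truth.

Emulates the structure of an older occupational cohort wearing wrist
accelerometers: BMI groups (normal weight / overweight / obese), five
continuous metabolic risk markers plus medication flags, questionnaire
activity items as (MET, hours/week) pairs, demographic and behavioural
covariates, and objective weekly activity summaries.

The generative model is deliberately simple and fully configurable:

* a latent activity propensity ``A`` (standard normal after a configurable
  negative BMI gradient) drives the objective weekly acceleration, the
  bouted MVPA minutes, and — through a Gaussian copula calibrated to a
  target Spearman correlation — the questionnaire hours;
* each risk factor is Bernoulli with log-odds linear in BMI and in ``A``;
  the continuous marker is then drawn on the matching side of the clinical
  cutoff (a configurable share of flagged participants are instead
  medication-driven, with a healthy-side marker value);
* covariates are categorical draws at configurable frequencies, with a
  small rate of current-wave missingness backed by a prior-wave value to
  exercise carry-back.

Latent truth columns are prefixed ``true_`` / named ``latent_activity``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CohortParams", "RiskFactorParams", "generate_cohort"]


class CohortParamsError(ValueError):
    pass


@dataclass(frozen=True)
class RiskFactorParams:
    """One metabolic risk factor: prevalence and its BMI/activity slopes."""

    baseline_prevalence: float
    slope_bmi: float          # log-odds per kg/m^2 above the centring BMI
    slope_activity: float     # log-odds per SD of latent activity
    medication_share: float = 0.0  # share of flagged cases that are meds-driven

    def validate(self, name: str) -> None:
        if not 0.0 <= self.baseline_prevalence <= 1.0:
            raise CohortParamsError(f"{name}: prevalence must be in [0, 1]")
        if not 0.0 <= self.medication_share <= 1.0:
            raise CohortParamsError(f"{name}: medication_share must be in [0, 1]")
        for v in (self.slope_bmi, self.slope_activity):
            if not math.isfinite(v):
                raise CohortParamsError(f"{name}: slopes must be finite")


def _default_risk_factors() -> dict[str, RiskFactorParams]:
    return {
        "hypertension": RiskFactorParams(0.55, 0.13, -0.35, 0.35),
        "low_hdl": RiskFactorParams(0.40, 0.10, -0.25, 0.15),
        "high_glucose": RiskFactorParams(0.25, 0.10, -0.30, 0.10),
        "high_triglycerides": RiskFactorParams(0.14, 0.12, -0.30, 0.0),
        "insulin_resistance": RiskFactorParams(0.06, 0.20, -0.40, 0.0),
    }


def _default_bmi_groups() -> dict[str, tuple[float, float, float, float, float]]:
    # share, mean, sd, lower, upper (truncated normal per BMI band)
    return {
        "normal": (0.385, 22.8, 1.6, 18.5, 24.99),
        "overweight": (0.437, 27.2, 1.4, 25.0, 29.99),
        "obese": (0.178, 33.0, 3.0, 30.0, 50.0),
    }


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generative settings. Defaults are the study conditions
    the package is tested under: n = 3457, 23% female, ages 60–82, risk
    prevalence rising with BMI and falling with activity, questionnaire vs
    objective activity Spearman 0.30."""

    n: int = 3457
    seed: int = 0
    female_share: float = 0.23
    age_mean: float = 69.2
    age_sd: float = 5.6
    age_range: tuple[float, float] = (60.0, 82.0)
    nonwhite_share: float = 0.07
    bmi_groups: Mapping[str, tuple[float, float, float, float, float]] = field(
        default_factory=_default_bmi_groups)
    bmi_centre: float = 26.5
    activity_bmi_slope: float = 0.06   # latent activity drops per kg/m^2
    risk_factors: Mapping[str, RiskFactorParams] = field(
        default_factory=_default_risk_factors)
    spearman_target: float = 0.30
    enmo_mean_mg: float = 23.5
    enmo_sd_mg: float = 6.0
    mvpa_log_mean: float = 4.46        # log minutes/week at A = 0
    mvpa_log_sd_activity: float = 0.8
    mvpa_log_sd_noise: float = 0.6
    mvpa_setting_factors: Mapping[tuple[float, int], float] = field(
        default_factory=lambda: {(100.0, 10): 1.0, (100.0, 1): 1.6,
                                 (120.0, 10): 0.55, (120.0, 1): 0.88})
    missing_current_rate: float = 0.02

    def validate(self) -> None:
        if self.n < 1:
            raise CohortParamsError("n must be >= 1")
        for p in (self.female_share, self.nonwhite_share, self.missing_current_rate):
            if not 0.0 <= p <= 1.0:
                raise CohortParamsError("probabilities must be in [0, 1]")
        shares = [v[0] for v in self.bmi_groups.values()]
        if abs(sum(shares) - 1.0) > 1e-9:
            raise CohortParamsError("BMI group shares must sum to 1")
        if not -1.0 < self.spearman_target < 1.0:
            raise CohortParamsError("spearman_target must be in (-1, 1)")
        for v in (self.age_mean, self.age_sd, self.enmo_mean_mg, self.enmo_sd_mg,
                  self.mvpa_log_mean, self.mvpa_log_sd_activity,
                  self.mvpa_log_sd_noise, self.activity_bmi_slope):
            if not math.isfinite(v):
                raise CohortParamsError("parameters must be finite")
        for name, rf in self.risk_factors.items():
            rf.validate(name)


# clinical cutoffs used when drawing marker values on the intended side
HDL_CUTOFF = {"male": 1.03, "female": 1.29}
SBP_CUTOFF, DBP_CUTOFF = 130.0, 85.0
GLUCOSE_CUTOFF = 5.6
TG_CUTOFF = 1.7
HOMA_IR_CUTOFF = 5.12

#: fixed MET menu for the synthetic questionnaire items
MET_MENU = {"walking": 3.5, "gardening": 4.0, "sports": 6.0, "housework": 2.5}


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate one cohort table (one row per participant).

    Deterministic for a fixed ``params.seed``. Latent truth columns:
    ``latent_activity`` (the standardized propensity), ``true_<factor>``
    per risk factor and ``true_rf_count``.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    ids = np.array([f"P{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < params.female_share, "female", "male")
    age = _truncnorm(rng, params.age_mean, params.age_sd, *params.age_range, n)
    ethnicity = np.where(rng.random(n) < params.nonwhite_share, "nonwhite", "white")

    groups = list(params.bmi_groups)
    shares = np.array([params.bmi_groups[g][0] for g in groups])
    grp = rng.choice(len(groups), size=n, p=shares / shares.sum())
    bmi = np.empty(n)
    for gi, g in enumerate(groups):
        _, mean, sd, lo, hi = params.bmi_groups[g]
        idx = np.nonzero(grp == gi)[0]
        bmi[idx] = _truncnorm(rng, mean, sd, lo, hi, len(idx))

    # latent activity propensity, standardized after the BMI gradient
    raw_a = rng.standard_normal(n) - params.activity_bmi_slope * (bmi - params.bmi_centre)
    activity = (raw_a - raw_a.mean()) / raw_a.std(ddof=1)

    # questionnaire latent via Gaussian copula calibrated to the target
    # Spearman: rho_s = (6/pi) asin(rho_p / 2)
    rho_p = 2.0 * math.sin(math.pi * params.spearman_target / 6.0)
    q_latent = rho_p * activity + math.sqrt(1 - rho_p ** 2) * rng.standard_normal(n)

    # objective summaries (monotone in the latent propensity)
    enmo = np.clip(params.enmo_mean_mg + params.enmo_sd_mg * activity, 1.0, None)
    mvpa_core = np.exp(params.mvpa_log_mean
                       + params.mvpa_log_sd_activity * activity
                       + params.mvpa_log_sd_noise * rng.standard_normal(n))

    # questionnaire items: near-universal housework plus an "active" block
    # (walking/gardening/sports in fixed shares), both monotone in q_latent
    housework_h = np.exp(1.8 + 0.3 * q_latent)
    active_h = np.exp(1.03 + 1.0 * q_latent)
    items = {
        "activity_walking_hours": 0.57 * active_h,
        "activity_gardening_hours": 0.29 * active_h,
        "activity_sports_hours": 0.14 * active_h,
        "activity_housework_hours": housework_h,
    }

    df = pd.DataFrame({"participant_id": ids, "sex": sex, "age": age,
                       "ethnicity": ethnicity, "bmi": bmi,
                       "bmi_group": np.array(groups)[grp]})
    for col, vals in items.items():
        df[col] = vals

    # --- metabolic risk factors ------------------------------------------
    # user-supplied factors override the defaults; the five markers below
    # are always drawn so phenotyping sees complete records
    risk = {**_default_risk_factors(), **dict(params.risk_factors)}
    unknown = set(risk) - set(_default_risk_factors())
    if unknown:
        raise CohortParamsError(f"unknown risk factors: {sorted(unknown)}")
    flags = {}
    for name, rf in risk.items():
        if rf.baseline_prevalence in (0.0, 1.0) or \
                (rf.slope_bmi == 0 and rf.slope_activity == 0):
            p = np.full(n, rf.baseline_prevalence)
        else:
            logit0 = math.log(rf.baseline_prevalence / (1 - rf.baseline_prevalence))
            p = _sigmoid(logit0 + rf.slope_bmi * (bmi - params.bmi_centre)
                         + rf.slope_activity * activity)
        flag = rng.random(n) < p
        meds = flag & (rng.random(n) < rf.medication_share)
        flags[name] = (flag, meds)

    # HDL: low is the risk side, sex-specific cutoff
    hdl_flag, hdl_meds = flags["low_hdl"]
    value_low = hdl_flag & ~hdl_meds
    cut = np.where(sex == "female", HDL_CUTOFF["female"], HDL_CUTOFF["male"])
    hdl = np.empty(n)
    lo_idx = np.nonzero(value_low)[0]
    hi_idx = np.nonzero(~value_low)[0]
    hdl[lo_idx] = cut[lo_idx] - np.abs(_truncnorm(rng, 0.2, 0.12, 0.01, 0.6, len(lo_idx)))
    hdl[hi_idx] = cut[hi_idx] + np.abs(_truncnorm(rng, 0.4, 0.3, 0.001, 1.5, len(hi_idx)))
    df["hdl"] = hdl
    df["lipid_meds"] = hdl_meds

    bp_flag, bp_meds = flags["hypertension"]
    value_bp = bp_flag & ~bp_meds
    sbp = _truncnorm(rng, 120.0, 7.0, 95.0, SBP_CUTOFF - 0.01, n)
    dbp = _truncnorm(rng, 70.0, 6.0, 50.0, DBP_CUTOFF - 0.01, n)
    k = int(value_bp.sum())
    sbp[value_bp] = _truncnorm(rng, 140.0, 9.0, SBP_CUTOFF, 200.0, k)
    dbp[value_bp] = _truncnorm(rng, 78.0, 8.0, 55.0, 110.0, k)
    df["sbp"], df["dbp"] = sbp, dbp
    df["bp_meds"] = bp_meds

    glu_flag, glu_meds = flags["high_glucose"]
    value_glu = glu_flag & ~glu_meds
    glucose = _truncnorm(rng, 5.1, 0.25, 3.8, GLUCOSE_CUTOFF - 0.01, n)
    glucose[value_glu] = _truncnorm(rng, 6.2, 0.8, GLUCOSE_CUTOFF, 12.0,
                                    int(value_glu.sum()))
    df["fasting_glucose"] = glucose
    df["diabetes_meds"] = glu_meds

    tg_flag, _ = flags["high_triglycerides"]
    tg = _truncnorm(rng, 1.1, 0.3, 0.3, TG_CUTOFF - 0.01, n)
    tg[tg_flag] = _truncnorm(rng, 2.2, 0.5, TG_CUTOFF, 6.0, int(tg_flag.sum()))
    df["triglycerides"] = tg

    ir_flag, _ = flags["insulin_resistance"]
    homa = _truncnorm(rng, 2.0, 1.2, 0.3, HOMA_IR_CUTOFF, n)
    homa[ir_flag] = _truncnorm(rng, 7.5, 2.5, HOMA_IR_CUTOFF + 0.01, 30.0,
                               int(ir_flag.sum()))
    df["homa_ir"] = homa

    rf_count = np.zeros(n, dtype=int)
    for name, (flag, _) in flags.items():
        df[f"true_{name}"] = flag
        rf_count += flag
    df["true_rf_count"] = rf_count

    # --- covariates -------------------------------------------------------
    df["occ_position"] = rng.choice(["administrative", "professional", "clerical"],
                                    size=n, p=[0.45, 0.47, 0.08])
    df["smoking"] = rng.choice(["never", "ex", "current"], size=n, p=[0.5, 0.45, 0.05])
    abstainer = rng.random(n) < 0.2
    units = np.round(rng.gamma(2.0, 5.0, n), 1)
    units[abstainer] = 0.0
    df["alcohol_units"] = units
    df["fruit_veg"] = rng.choice(["less_than_daily", "daily", "twice_or_more"],
                                 size=n, p=[0.2, 0.5, 0.3])
    df["milk"] = rng.choice(["whole", "semi_skimmed", "skimmed_or_other"],
                            size=n, p=[0.08, 0.6, 0.32])
    df["bread"] = rng.choice(["white", "mixed_or_none", "wholemeal_or_brown"],
                             size=n, p=[0.17, 0.25, 0.58])
    df["sleep_category"] = rng.choice(["<=5h", "6h", "7h", "8h", ">=9h"],
                                      size=n, p=[0.08, 0.25, 0.4, 0.23, 0.04])
    df["limiting_illness"] = rng.choice(["not_at_all", "a_little", "a_lot"],
                                        size=n, p=[0.62, 0.22, 0.16])

    # prior-wave copies plus current-wave missingness (exercises carry-back)
    for col in ("occ_position", "smoking"):
        df[f"{col}_prior"] = df[col]
        drop = rng.random(n) < params.missing_current_rate
        df.loc[drop, col] = np.nan

    # --- objective activity summaries --------------------------------------
    df["accel_weekly_enmo_mg"] = enmo
    for (thr, bout), factor in params.mvpa_setting_factors.items():
        df[f"accel_mvpa_min_wk_{int(thr)}_{int(bout)}"] = mvpa_core * factor

    df["latent_activity"] = activity
    return df
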