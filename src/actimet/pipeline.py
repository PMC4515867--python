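"""End-to-end study orchestration.

``run_study`` wires the modules together on a synthetic cohort: generate
(or load) the cohort table, exercise the raw-signal chain on a subset of
participants against generator truth, classify phenotypes, score the
questionnaire, and fit the analysis models:

* a descriptive table by the six metabolic/BMI phenotypes;
* standardized total-activity differences vs healthy normal weight
  (questionnaire and accelerometer, two adjustment sets, with AIC);
* modified-Poisson prevalence ratios for meeting the WHO
  moderate-to-vigorous activity recommendation, under both the healthy
  normal weight and the unhealthy obese reference;
* per-risk-factor prevalence ratios per SD of total activity;
* sensitivity PR tables across MVPA settings (100/120 mg x 10/1-min bouts).

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import questionnaire as qn
from . import stats as st
from .accelerometry import (
    DEFAULT_MVPA_SETTINGS,
    WHO_MVPA_MIN_PER_WEEK,
    summarize_recording,
)
from .phenotyping import PHENOTYPE_LEVELS, phenotype_cohort
from .synthetic.cohort import CohortParams, generate_cohort
from .synthetic.signal import SignalProfile, generate_raw_recording

logger = logging.getLogger(__name__)

MODEL1_COVARIATES = ("age", "sex", "ethnicity")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "occ_position", "diet_cat", "smoking", "alcohol_cat",
    "sleep_category", "limiting_illness")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one end-to-end run."""

    seed: int = 0
    n_participants: int = 3457
    n_signal_subjects: int = 8
    signal_days: int = 8
    signal_sampling_rate_hz: float = 25.0
    epoch_length_s: float = 5.0
    mvpa_settings: tuple[tuple[float, int], ...] = DEFAULT_MVPA_SETTINGS
    nonwear_sd_threshold_mg: float = 13.0
    nonwear_range_threshold_mg: float = 50.0
    output_dir: str | None = None
    cohort_overrides: Mapping = field(default_factory=dict)
    make_figures: bool = True

    def validate(self) -> None:
        if not self.mvpa_settings:
            raise ConfigError("at least one MVPA (threshold, bout) setting required")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_signal_subjects < 0:
            raise ConfigError("n_signal_subjects must be >= 0")
        if self.epoch_length_s <= 0:
            raise ConfigError("epoch_length_s must be positive")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "mvpa_settings" in raw:
            raw["mvpa_settings"] = tuple(
                (float(t), int(b)) for t, b in raw["mvpa_settings"])
        return cls(**raw)


@dataclass
class StudyResults:
    cohort: pd.DataFrame
    descriptive: pd.DataFrame
    activity_differences: pd.DataFrame
    who_prevalence_ratios: pd.DataFrame
    risk_factor_prs: pd.DataFrame
    sensitivity_prs: pd.DataFrame
    signal_recovery: pd.DataFrame
    exclusions: pd.DataFrame
    log: dict


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts, percentages and mean +/- SD by the six phenotypes.

    Returns a numeric table: one column per phenotype plus ``overall``;
    rows are ``n``, ``female_pct``, per-variable ``<var>_mean``/``<var>_sd``
    where present, and WHO-recommendation prevalences per method. Empty
    groups are reported with n = 0, not dropped.
    """
    if "phenotype6" not in cohort.columns:
        raise ConfigError("cohort must be phenotyped (phenotype6 column)")
    groups = [g for g in PHENOTYPE_LEVELS]
    columns: dict[str, dict[str, float]] = {}

    def stats_for(sub: pd.DataFrame) -> dict[str, float]:
        n = len(sub)
        row: dict[str, float] = {"n": float(n)}
        if "sex" in sub.columns:
            row["female_pct"] = 100.0 * (sub["sex"] == "female").mean() if n else 0.0
        for var in ("age", "bmi", "q_total_met_h_wk", "accel_weekly_enmo_mg"):
            if var in sub.columns and n:
                row[f"{var}_mean"] = float(sub[var].mean())
                row[f"{var}_sd"] = float(sub[var].std(ddof=1)) if n > 1 else 0.0
        for flag, label in (("q_meets_who", "who_questionnaire_pct"),
                            ("accel_meets_who", "who_accelerometer_pct")):
            if flag in sub.columns:
                row[label] = 100.0 * sub[flag].mean() if n else 0.0
        return row

    for g in groups:
        columns[g] = stats_for(cohort[cohort["phenotype6"] == g])
    columns["overall"] = stats_for(cohort)
    table = pd.DataFrame(columns)
    return table.loc[[r for r in table.index], groups + ["overall"]]


# ---------------------------------------------------------------------------
# signal-chain recovery on a participant subset
# ---------------------------------------------------------------------------


def _profile_for_participant(row: pd.Series, config: StudyConfig,
                             seed: int) -> SignalProfile:
    """Derive a signal recipe from a cohort row.

    Awake background level is solved so the weekly ENMO truth matches the
    participant's tabulated value; their main-setting MVPA minutes are
    injected as one 150 mg bout per day (capped at a plausible length).
    """
    daily_mvpa = min(float(row["accel_mvpa_min_wk_100_10"]) / 7.0, 120.0)
    daily_mvpa = max(round(daily_mvpa), 0)
    bouts = []
    if daily_mvpa >= 10:  # shorter bouts would not pass the 10-min rule
        for day in range(config.signal_days):
            bouts.append((day, 10.0, float(daily_mvpa), 150.0))
    # weekly ENMO = sleep share * 0 + bout share * 150 + awake share * bg
    awake_h = 16.0
    bout_h = daily_mvpa / 60.0
    target = float(row["accel_weekly_enmo_mg"])
    bg = (24.0 * target - bout_h * 150.0) / (awake_h - bout_h)
    bg = max(bg, 1.0)
    return SignalProfile(
        days=config.signal_days,
        sampling_rate_hz=config.signal_sampling_rate_hz,
        background_enmo_mg=bg,
        mvpa_bouts=tuple(bouts),
        nonwear_intervals=((1, 17.0, 120.0), (4, 12.0, 60.0)),
        axis_gain=(1.015, 0.99, 1.005),
        axis_offset_g=(0.012, -0.008, 0.005),
        seed=seed,
    )


def signal_recovery(cohort: pd.DataFrame, config: StudyConfig,
                    seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """Run the raw-signal chain on a subset; report truth vs pipeline."""
    rows = []
    n = min(config.n_signal_subjects, len(cohort))
    seeds = seed_seq.generate_state(max(n, 1)) % (2 ** 31)
    for i in range(n):
        row = cohort.iloc[i]
        profile = _profile_for_participant(row, config, int(seeds[i]))
        rec, truth = generate_raw_recording(
            profile, epoch_length_s=config.epoch_length_s,
            mvpa_settings=config.mvpa_settings,
            participant_id=str(row["participant_id"]))
        summary, reason = summarize_recording(
            rec, epoch_length_s=config.epoch_length_s,
            mvpa_settings=config.mvpa_settings,
            nonwear_kwargs={
                "sd_threshold_mg": config.nonwear_sd_threshold_mg,
                "range_threshold_mg": config.nonwear_range_threshold_mg,
            })
        if summary is None:
            rows.append({"participant_id": row["participant_id"],
                         "status": reason})
            continue
        det_nw, true_nw = ~summary.wear_mask.wear, ~truth.wear
        union = (det_nw | true_nw).sum()
        jaccard = float((det_nw & true_nw).sum() / union) if union else 1.0
        rec_row = {
            "participant_id": row["participant_id"],
            "status": "ok",
            "true_weekly_enmo_mg": truth.weekly_enmo_mg,
            "pipeline_weekly_enmo_mg": summary.weekly_mean_enmo_mg,
            "enmo_error_mg": summary.weekly_mean_enmo_mg - truth.weekly_enmo_mg,
            "nonwear_jaccard": jaccard,
            "imputed_fraction": summary.imputed_fraction,
        }
        for key, true_min in truth.bouted_mvpa_min_per_week.items():
            tag = f"{int(key[0])}_{int(key[1])}"
            rec_row[f"true_mvpa_{tag}"] = true_min
            rec_row[f"pipeline_mvpa_{tag}"] = summary.mvpa_min_per_week[key]
            rec_row[f"mvpa_error_{tag}"] = summary.mvpa_min_per_week[key] - true_min
        rows.append(rec_row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis models
# ---------------------------------------------------------------------------


def _attach_scores(cohort: pd.DataFrame,
                   settings: Sequence[tuple[float, int]]) -> pd.DataFrame:
    df = qn.score_cohort(cohort)
    main = settings[0]
    df["accel_meets_who"] = (
        df[f"accel_mvpa_min_wk_{int(main[0])}_{int(main[1])}"]
        >= WHO_MVPA_MIN_PER_WEEK)
    for thr, bout in settings:
        df[f"accel_meets_who_{int(thr)}_{int(bout)}"] = (
            df[f"accel_mvpa_min_wk_{int(thr)}_{int(bout)}"]
            >= WHO_MVPA_MIN_PER_WEEK)
    df["z_q_activity"] = st.standardize(df["q_total_met_h_wk"])
    df["z_accel_activity"] = st.standardize(df["accel_weekly_enmo_mg"])
    return df


def activity_difference_models(df: pd.DataFrame) -> pd.DataFrame:
    """Standardized activity differences across phenotypes, both methods."""
    out = []
    for method, outcome in (("questionnaire", "z_q_activity"),
                            ("accelerometer", "z_accel_activity")):
        for model_id, covs in (("model1", MODEL1_COVARIATES),
                               ("model2", MODEL2_COVARIATES)):
            spec = st.ModelSpec(outcome, "phenotype6", covs,
                                reference="healthy_normal",
                                model_id=f"{method}_{model_id}")
            ests = st.linear_differences(spec, df)
            frame = st.estimates_frame(ests)
            frame.insert(0, "method", method)
            out.append(frame)
    return pd.concat(out, ignore_index=True)


def who_pr_models(df: pd.DataFrame) -> pd.DataFrame:
    """WHO-recommendation PRs under both reference groups, both methods."""
    out = []
    for method, outcome in (("questionnaire", "q_meets_who"),
                            ("accelerometer", "accel_meets_who")):
        y = df[outcome].astype(float)
        for model_id, covs in (("model1", MODEL1_COVARIATES),
                               ("model2", MODEL2_COVARIATES)):
            for ref in ("healthy_normal", "unhealthy_obese"):
                spec = st.ModelSpec("_y", "phenotype6", covs, reference=ref,
                                    model_id=f"{method}_{model_id}_ref_{ref}")
                data = df.assign(_y=y)
                frame = st.estimates_frame(st.robust_poisson_pr(spec, data))
                frame.insert(0, "reference", ref)
                frame.insert(0, "method", method)
                out.append(frame)
    return pd.concat(out, ignore_index=True)


def risk_factor_pr_models(df: pd.DataFrame) -> pd.DataFrame:
    """PR per SD of total activity for each risk factor and for obesity."""
    outcomes = {f"rf_{name}": f"rf_{name}" for name in
                ("hypertension", "low_hdl", "high_triglycerides",
                 "high_glucose", "insulin_resistance")}
    outcomes["obesity"] = "obesity"
    data = df.assign(obesity=(df["bmi_cat"] == "obese"))
    out = []
    for method, exposure in (("questionnaire", "z_q_activity"),
                             ("accelerometer", "z_accel_activity")):
        for label, col in outcomes.items():
            spec = st.ModelSpec("_y", exposure, MODEL1_COVARIATES,
                                model_id=f"{method}_{label}")
            frame = st.estimates_frame(st.robust_poisson_pr(
                spec, data.assign(_y=data[col].astype(float))))
            frame.insert(0, "outcome", label)
            frame.insert(0, "method", method)
            out.append(frame)
    return pd.concat(out, ignore_index=True)


def sensitivity_pr_models(df: pd.DataFrame,
                          settings: Sequence[tuple[float, int]]) -> pd.DataFrame:
    """Accelerometer WHO PRs at every (threshold, bout length) setting."""
    out = []
    for thr, bout in settings:
        col = f"accel_meets_who_{int(thr)}_{int(bout)}"
        for ref in ("healthy_normal", "unhealthy_obese"):
            spec = st.ModelSpec("_y", "phenotype6", MODEL2_COVARIATES,
                                reference=ref,
                                model_id=f"accel_{int(thr)}mg_{int(bout)}min_ref_{ref}")
            frame = st.estimates_frame(st.robust_poisson_pr(
                spec, df.assign(_y=df[col].astype(float))))
            frame.insert(0, "reference", ref)
            frame.insert(0, "bout_min", bout)
            frame.insert(0, "threshold_mg", thr)
            out.append(frame)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def _point_interval_figure(frame: pd.DataFrame, value: str, path: Path,
                           title: str, hline: float | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    labels = [f"{m}:{t}" for m, t in zip(frame["model_id"], frame["term"])]
    x = np.arange(len(frame))
    ax.errorbar(x, frame[value],
                yerr=[frame[value] - frame["ci_low"],
                      frame["ci_high"] - frame[value]],
                fmt="o", capsize=3)
    if hline is not None:
        ax.axhline(hline, color="grey", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel(value)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_study(config: StudyConfig) -> StudyResults:
    """Run the full pipeline; see the module docstring for the outputs."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    cohort_seq, signal_seq = master.spawn(2)

    overrides = dict(config.cohort_overrides)
    overrides.setdefault("n", config.n_participants)
    overrides["seed"] = int(cohort_seq.generate_state(1)[0] % (2 ** 31))
    params = CohortParams(**overrides)
    cohort = generate_cohort(params)
    logger.info("generated cohort of %d participants", len(cohort))

    recovery = signal_recovery(cohort, config, signal_seq)

    phenotyped, excluded = phenotype_cohort(cohort)
    scored = _attach_scores(phenotyped, config.mvpa_settings)

    desc = descriptive_table(scored)
    diffs = activity_difference_models(scored)
    who_prs = who_pr_models(scored)
    rf_prs = risk_factor_pr_models(scored)
    sens = sensitivity_pr_models(scored, config.mvpa_settings)

    log = {
        "seed": config.seed,
        "n_generated": int(len(cohort)),
        "n_analyzed": int(len(scored)),
        "n_excluded": int(len(excluded)),
        "group_sizes": {g: int((scored["phenotype6"] == g).sum())
                        for g in PHENOTYPE_LEVELS},
        "signal_subjects": int(len(recovery)),
        "mean_imputed_fraction": (float(recovery["imputed_fraction"].mean())
                                  if "imputed_fraction" in recovery else None),
    }

    results = StudyResults(scored, desc, diffs, who_prs, rf_prs, sens,
                           recovery, excluded, log)

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        scored.to_csv(outdir / "cohort_phenotyped.csv", index=False)
        desc.to_csv(outdir / "table1_descriptive.csv")
        diffs.to_csv(outdir / "activity_differences.csv", index=False)
        who_prs.to_csv(outdir / "who_prevalence_ratios.csv", index=False)
        rf_prs.to_csv(outdir / "risk_factor_prs.csv", index=False)
        sens.to_csv(outdir / "sensitivity_prs.csv", index=False)
        recovery.to_csv(outdir / "signal_recovery.csv", index=False)
        excluded.to_csv(outdir / "exclusions.csv", index=False)
        with open(outdir / "run.log", "w") as fh:
            json.dump(log, fh, indent=2)
        if config.make_figures:
            _point_interval_figure(
                diffs, "estimate", outdir / "fig_activity_differences.png",
                "Standardized activity differences vs healthy normal weight",
                hline=0.0)
            _point_interval_figure(
                rf_prs, "estimate", outdir / "fig_risk_factor_prs.png",
                "Risk-factor prevalence ratios per SD of total activity",
                hline=1.0)
    return results
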