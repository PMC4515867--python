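"""Statistical layer: z-scores, adjusted linear differences, modified
Poisson prevalence ratios with sandwich variance, AIC, Spearman, Bonferroni.

Linear models are ordinary least squares with classical standard errors;
prevalence ratios come from a log-link Poisson likelihood fit to the binary
outcome with an HC0 (heteroskedasticity-robust) covariance — the standard
"modified Poisson" recipe, which avoids the odds-ratio inflation of
logistic models when the outcome is common. Confidence intervals for PRs
are normal-approximation intervals on the log scale, exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

Z_95 = sps.norm.ppf(0.975)


class StatsError(ValueError):
    pass


class RankDeficientError(StatsError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``exposure`` is either a categorical column (each non-reference level
    gets an indicator, ``reference`` picking the baseline) or a continuous
    column (a single per-unit coefficient). ``covariates`` are entered
    reference-coded when categorical (first category observed = reference)
    and linearly when numeric.
    """

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    reference: str | None = None
    model_id: str = "model"


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    aic: float
    model_id: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise StatsError("CI must bracket the estimate")


# ---------------------------------------------------------------------------


def standardize(values: Sequence[float], ddof: int = 1) -> np.ndarray:
    """z-scores with (by default) the sample (n-1) SD; mean 0, SD 1."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise StatsError("standardize needs a 1-D array of length >= 2")
    if not np.isfinite(x).all():
        raise StatsError("values must be finite")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise StatsError("cannot standardize a constant input")
    return (x - x.mean()) / sd


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    if m < 1:
        raise StatsError("m must be >= 1")
    return alpha / m


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatsError("spearman needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("spearman is undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def aic(fit_or_loglik, n_params: int | None = None) -> float:
    """Akaike Information Criterion, 2k - 2 log L (lower is better)."""
    if n_params is None:
        fit = fit_or_loglik
        return float(2 * (fit.df_model + getattr(fit, "k_constant", 1))
                     - 2 * fit.llf)
    return float(2 * n_params - 2 * fit_or_loglik)


# ---------------------------------------------------------------------------
# design matrix construction
# ---------------------------------------------------------------------------


def _is_categorical(s: pd.Series) -> bool:
    return (isinstance(s.dtype, pd.CategoricalDtype)
            or s.dtype == object or s.dtype == bool)


def _exposure_columns(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    s = data[spec.exposure]
    if _is_categorical(s):
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = [lv for lv in s.cat.categories if lv in set(s.dropna())]
        else:
            levels = list(pd.unique(s.dropna()))
        ref = spec.reference if spec.reference is not None else levels[0]
        if ref not in levels:
            raise StatsError(f"reference level {ref!r} not found in "
                             f"{spec.exposure}")
        terms = [lv for lv in levels if lv != ref]
        cols = {f"{spec.exposure}[{lv}]": (s == lv).astype(float) for lv in terms}
        return pd.DataFrame(cols, index=data.index), list(cols)
    return pd.DataFrame({spec.exposure: s.astype(float)}), [spec.exposure]


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Outcome vector, design matrix (with intercept) and exposure terms."""
    for col in (spec.outcome, spec.exposure, *spec.covariates):
        if col not in data.columns:
            raise StatsError(f"column {col!r} not in data")
    sub = data[[spec.outcome, spec.exposure, *spec.covariates]].dropna()
    y = sub[spec.outcome].astype(float)
    expo, terms = _exposure_columns(sub, spec)
    parts = [pd.Series(1.0, index=sub.index, name="Intercept"), expo]
    for cov in spec.covariates:
        s = sub[cov]
        if _is_categorical(s):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).rename(cov))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                collinear.append(name)
        raise RankDeficientError(f"design is rank deficient; collinear "
                                 f"columns: {collinear}")
    return y, X, terms


def _collect(fit, terms: list[str], n: int, model_id: str,
             transform=None) -> list[EffectEstimate]:
    conf = fit.conf_int(alpha=0.05)
    out = []
    f = transform or (lambda v: v)
    for term in terms:
        out.append(EffectEstimate(
            term=term,
            estimate=float(f(fit.params[term])),
            ci_low=float(f(conf.loc[term, 0])),
            ci_high=float(f(conf.loc[term, 1])),
            p=float(fit.pvalues[term]),
            n=n,
            aic=float(fit.aic),
            model_id=model_id,
        ))
    return out


def estimates_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Tidy results table (term, estimate, ci_low, ci_high, p, n, aic, model_id)."""
    return pd.DataFrame([e.__dict__ for e in estimates])


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------


def linear_differences(spec: ModelSpec, data: pd.DataFrame) -> list[EffectEstimate]:
    """Covariate-adjusted mean differences in the (standardized) outcome.

    OLS with classical standard errors; one estimate per non-reference
    exposure level (or a single slope for a continuous exposure).
    """
    y, X, terms = build_design(data, spec)
    fit = sm.OLS(y, X).fit()
    return _collect(fit, terms, len(y), spec.model_id)


def robust_poisson_pr(spec: ModelSpec, data: pd.DataFrame,
                      maxiter: int = 100, tol: float = 1e-10) -> list[EffectEstimate]:
    """Prevalence ratios from a modified Poisson model.

    Log-link Poisson likelihood on the binary outcome, fitted by IRLS;
    HC0 sandwich covariance; Wald p-values; PR and its CI exponentiated
    from the log scale.
    """
    y, X, terms = build_design(data, spec)
    vals = set(np.unique(y))
    if not vals <= {0.0, 1.0}:
        raise StatsError(f"outcome {spec.outcome!r} must be binary 0/1")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        fit = model.fit(cov_type="HC0", maxiter=maxiter, tol=tol)
    except Exception as err:  # pragma: no cover - separation etc.
        raise StatsError(f"modified Poisson fit failed: {err}") from err
    if not fit.converged:
        raise StatsError(
            f"modified Poisson IRLS did not converge in {maxiter} iterations "
            f"(deviance trace: {getattr(fit, 'fit_history', {}).get('deviance', '?')})")
    return _collect(fit, terms, len(y), spec.model_id, transform=np.exp)


def prevalence_ratio_2x2(exposed_cases: int, exposed_n: int,
                         reference_cases: int, reference_n: int) -> dict[str, float]:
    """Closed-form risk ratio and delta-method SE for an unadjusted 2x2.

    PR = (a/n1) / (c/n0); SE(log PR) = sqrt((1-p1)/(n1 p1) + (1-p0)/(n0 p0)).
    Provided as an analytic cross-check of :func:`robust_poisson_pr`.
    """
    p1 = exposed_cases / exposed_n
    p0 = reference_cases / reference_n
    if p1 <= 0 or p0 <= 0:
        raise StatsError("both groups need at least one case")
    pr = p1 / p0
    se = np.sqrt((1 - p1) / (exposed_n * p1) + (1 - p0) / (reference_n * p0))
    return {
        "pr": pr,
        "se_log": float(se),
        "ci_low": float(np.exp(np.log(pr) - Z_95 * se)),
        "ci_high": float(np.exp(np.log(pr) + Z_95 * se)),
    }
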