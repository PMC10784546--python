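"""Generalized propensity scores, IPW, balance diagnostics, effect estimates.

For a continuous treatment T with covariates X, the propensity model is a
linear mixed model (random intercept per participant); the generalized
propensity score is the normal density of the residual, and the inverse
probability weight is its reciprocal (optionally stabilized by the marginal
density of T and truncated at the [1st, 99th] weight percentiles).  For the
multi-category elevated-meal-count treatment, a multinomial model supplies
P(T = observed | X).  Balance is checked with weighted treatment-covariate
correlations (|r| < 0.1) for continuous T and the maximum pairwise weighted
standardized mean difference (< 0.2) for categorical T.  Outcome models are
weighted regressions with a participant-level multilevel structure
(exchangeable-cluster GEE: linear for continuous outcomes, logistic for the
elevated/normal label), made doubly robust by including the covariates
whenever balance is not fully achieved (or always, by option).

Significance convention: p < 0.01.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.01
CORRELATION_BALANCE_THRESHOLD = 0.1
SMD_BALANCE_THRESHOLD = 0.2
TRUNCATION_PERCENTILES = (1.0, 99.0)


@dataclass
class CausalTask:
    """Names one estimation problem on an analysis table."""

    treatment: str
    treatment_type: str  # "continuous" | "categorical"
    covariates: list[str]
    outcome: str
    outcome_type: str = "continuous"  # "continuous" | "binary"
    group: str = "participant_id"

    def __post_init__(self) -> None:
        if self.treatment in self.covariates:
            raise ValueError("treatment must not appear among covariates")
        if self.treatment_type not in ("continuous", "categorical"):
            raise ValueError(f"unknown treatment type {self.treatment_type!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome type {self.outcome_type!r}")

    def check_columns(self, table: pd.DataFrame) -> None:
        needed = {self.treatment, self.outcome, self.group, *self.covariates}
        missing = needed - set(table.columns)
        if missing:
            raise KeyError(f"analysis table is missing columns {sorted(missing)}")


@dataclass
class WeightInfo:
    model: str
    stabilized: bool
    n_truncated: int
    fallback_fixed_effects: bool = False
    note: str = ""


@dataclass
class BalanceReport:
    metric: str  # "correlation" | "smd"
    threshold: float
    before: dict[str, float] = field(default_factory=dict)
    after: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(abs(v) < self.threshold for v in self.after.values())

    @property
    def passed_before(self) -> bool:
        return all(abs(v) < self.threshold for v in self.before.values())


@dataclass
class EffectEstimate:
    analysis: str
    term: str
    estimate: float
    se: float
    p_value: float
    doubly_robust: bool
    n: int
    balance_passed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value must be in (0, 1], got {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


# ---------------------------------------------------------------------------
# propensity weights


def _truncate(weights: np.ndarray, percentiles=TRUNCATION_PERCENTILES) -> tuple[np.ndarray, int]:
    lo, hi = np.percentile(weights, percentiles)
    clipped = np.clip(weights, lo, hi)
    return clipped, int(np.sum((weights < lo) | (weights > hi)))


def _fit_mixed_or_ols(y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """Random-intercept linear model with an OLS fallback on failure.

    Returns (fitted_values, residual_sd, used_fallback).
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True, maxiter=300)
        if not np.all(np.isfinite(fit.params)):
            raise ValueError("non-finite mixed-model parameters")
        return np.asarray(fit.fittedvalues), float(np.sqrt(fit.scale)), False
    except Exception as exc:  # noqa: BLE001 - any optimizer failure
        logger.warning("mixed propensity model failed (%s); using fixed effects", exc)
        fit = sm.OLS(y, exog).fit()
        return np.asarray(fit.fittedvalues), float(np.sqrt(fit.scale)), True


def propensity_weights_continuous(
    table: pd.DataFrame,
    task: CausalTask,
    stabilized: bool = True,
    truncate: bool = True,
) -> tuple[np.ndarray, WeightInfo]:
    """IPW weights for a continuous treatment via a normal-density GPS.

    Weight_i = f(T_i | marginal) / f(T_i | X_i, participant) when stabilized,
    else 1 / f(T_i | X_i, participant).
    """
    task.check_columns(table)
    t = table[task.treatment].to_numpy(dtype=float)
    x = table[task.covariates].to_numpy(dtype=float)
    # standardize for optimizer stability; residuals are scale-invariant
    x = (x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12)
    exog = sm.add_constant(x, has_constant="add")
    groups = table[task.group].to_numpy()
    fitted, sigma, fallback = _fit_mixed_or_ols(t, exog, groups)
    sigma = max(sigma, 1e-12)
    dens = stats.norm.pdf(t, loc=fitted, scale=sigma)
    dens = np.maximum(dens, 1e-300)
    weights = 1.0 / dens
    if stabilized:
        marg_sd = max(float(np.std(t, ddof=1)), 1e-12)
        weights = weights * stats.norm.pdf(t, loc=float(np.mean(t)), scale=marg_sd)
    n_trunc = 0
    if truncate:
        weights, n_trunc = _truncate(weights)
    info = WeightInfo(
        model="linear_mixed" if not fallback else "ols",
        stabilized=stabilized,
        n_truncated=n_trunc,
        fallback_fixed_effects=fallback,
    )
    return weights, info


def propensity_weights_categorical(
    table: pd.DataFrame,
    task: CausalTask,
    stabilized: bool = True,
    truncate: bool = True,
) -> tuple[np.ndarray, WeightInfo]:
    """IPW weights for a multi-category treatment via multinomial propensity.

    The propensity model is a multinomial logistic regression on the
    covariates (fixed effects; a light ridge keeps rare categories from
    producing separation).  Weight_i = 1 / P(T_i = observed | X_i), optionally
    multiplied by the marginal category share (stabilization).
    """
    task.check_columns(table)
    t = table[task.treatment].to_numpy()
    x = table[task.covariates].to_numpy(dtype=float)
    categories, t_codes = np.unique(t, return_inverse=True)
    note = ""
    counts = np.bincount(t_codes)
    if (counts < 2).any():
        rare = [str(categories[i]) for i in np.flatnonzero(counts < 2)]
        note = f"categories with <2 rows: {rare}"
        logger.warning("propensity model: %s", note)
    if len(categories) < 2:
        raise ValueError("treatment has a single category; weights undefined")
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit((x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12), t_codes)
    probs = clf.predict_proba((x - x.mean(axis=0)) / np.maximum(x.std(axis=0), 1e-12))
    p_obs = np.maximum(probs[np.arange(len(t_codes)), t_codes], 1e-12)
    weights = 1.0 / p_obs
    if stabilized:
        marginal = counts / counts.sum()
        weights = weights * marginal[t_codes]
    n_trunc = 0
    if truncate:
        weights, n_trunc = _truncate(weights)
    info = WeightInfo(
        model="multinomial_logit",
        stabilized=stabilized,
        n_truncated=n_trunc,
        note=note,
    )
    return weights, info


# ---------------------------------------------------------------------------
# balance


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = np.asarray(w, dtype=float)
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def _weighted_smd(x: np.ndarray, groups: np.ndarray, w: np.ndarray) -> float:
    """Max pairwise |weighted mean difference| / unadjusted pooled SD."""
    cats = np.unique(groups)
    means = {}
    sds = {}
    for c in cats:
        m = groups == c
        ww = w[m] / w[m].sum()
        means[c] = float(np.sum(ww * x[m]))
        sds[c] = float(np.var(x[m], ddof=1)) if m.sum() > 1 else 0.0
    worst = 0.0
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            pooled = np.sqrt((sds[a] + sds[b]) / 2.0)
            if pooled <= 0:
                continue
            worst = max(worst, abs(means[a] - means[b]) / pooled)
    return worst


def check_balance(
    table: pd.DataFrame, task: CausalTask, weights: np.ndarray
) -> BalanceReport:
    """Before/after covariate balance under the given weights."""
    task.check_columns(table)
    ones = np.ones(len(table))
    if task.treatment_type == "continuous":
        report = BalanceReport("correlation", CORRELATION_BALANCE_THRESHOLD)
        t = table[task.treatment].to_numpy(dtype=float)
        for cov in task.covariates:
            x = table[cov].to_numpy(dtype=float)
            if np.var(x) == 0:
                report.excluded.append(cov)
                continue
            report.before[cov] = weighted_pearson(t, x, ones)
            report.after[cov] = weighted_pearson(t, x, np.asarray(weights))
    else:
        report = BalanceReport("smd", SMD_BALANCE_THRESHOLD)
        groups = table[task.treatment].to_numpy()
        for cov in task.covariates:
            x = table[cov].to_numpy(dtype=float)
            if np.var(x) == 0:
                report.excluded.append(cov)
                continue
            report.before[cov] = _weighted_smd(x, groups, ones)
            report.after[cov] = _weighted_smd(x, groups, np.asarray(weights))
    return report


# ---------------------------------------------------------------------------
# outcome models


def _design(
    table: pd.DataFrame, task: CausalTask, doubly_robust: bool
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    if task.treatment_type == "categorical":
        cats = np.unique(table[task.treatment].to_numpy())
        for c in cats[1:]:  # reference = lowest category (0)
            cols.append((table[task.treatment].to_numpy() == c).astype(float))
            names.append(f"{task.treatment}[{cats[0]}->{c}]")
    else:
        cols.append(table[task.treatment].to_numpy(dtype=float))
        names.append(task.treatment)
    if doubly_robust:
        for cov in task.covariates:
            cols.append(table[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def estimate_effect(
    table: pd.DataFrame,
    task: CausalTask,
    weights: Optional[np.ndarray] = None,
    doubly_robust: Optional[bool] = None,
    balance: Optional[BalanceReport] = None,
    analysis: str = "",
    cov_type: str = "robust",
) -> list[EffectEstimate]:
    """Weighted cluster (participant) regression of outcome on treatment.

    ``doubly_robust=None`` resolves to True when the balance report fails
    any covariate (or is absent).  Returns one estimate per treatment term
    (per non-reference category for categorical treatments).
    """
    task.check_columns(table)
    if weights is None:
        weights = np.ones(len(table))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must all be positive")
    if doubly_robust is None:
        doubly_robust = balance is None or not balance.passed
    exog, names = _design(table, task, doubly_robust)
    y = table[task.outcome].to_numpy(dtype=float)
    groups = table[task.group].to_numpy()
    family = sm.families.Gaussian() if task.outcome_type == "continuous" else sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y,
            exog,
            groups=groups,
            family=family,
            cov_struct=sm.cov_struct.Exchangeable(),
            weights=weights,
        )
        fit = model.fit(cov_type=cov_type)
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise RuntimeError(
            "outcome model failed (non-finite estimates; possible separation "
            "in the logistic model)"
        )
    out: list[EffectEstimate] = []
    n_treat_terms = len(names) - 1 - (len(task.covariates) if doubly_robust else 0)
    for i in range(1, 1 + n_treat_terms):
        out.append(
            EffectEstimate(
                analysis=analysis or task.outcome,
                term=names[i],
                estimate=float(fit.params[i]),
                se=float(fit.bse[i]),
                p_value=float(np.clip(fit.pvalues[i], np.nextafter(0, 1), 1.0)),
                doubly_robust=bool(doubly_robust),
                n=len(table),
                balance_passed=None if balance is None else balance.passed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the four study analyses


@dataclass
class AnalysisResult:
    name: str
    estimates: list[EffectEstimate] = field(default_factory=list)
    balance: Optional[BalanceReport] = None
    weight_info: Optional[WeightInfo] = None
    note: str = ""

    @property
    def estimable(self) -> bool:
        return bool(self.estimates)


def _run_task(
    table: pd.DataFrame,
    task: CausalTask,
    name: str,
    stabilized: bool = True,
    truncate: bool = True,
    skip_ipw: bool = False,
    always_doubly_robust: bool = False,
) -> AnalysisResult:
    note = ""
    if task.treatment_type == "categorical":
        counts = table[task.treatment].value_counts()
        rare = counts[counts < 2].index.tolist()
        if rare:
            note = f"dropped singleton treatment categories {rare}"
            logger.warning("%s: %s", name, note)
            table = table[~table[task.treatment].isin(rare)].reset_index(drop=True)
    if table[task.treatment].nunique() < 2:
        return AnalysisResult(name=name, note="not estimable: treatment has one level")
    if skip_ipw:
        weights = np.ones(len(table))
        info = WeightInfo(model="none", stabilized=False, n_truncated=0,
                          note="IPW skipped: covariates already balanced")
    elif task.treatment_type == "continuous":
        weights, info = propensity_weights_continuous(table, task, stabilized, truncate)
    else:
        weights, info = propensity_weights_categorical(table, task, stabilized, truncate)
    balance = check_balance(table, task, weights)
    doubly_robust = True if (always_doubly_robust or skip_ipw) else None
    try:
        estimates = estimate_effect(
            table, task, weights, doubly_robust=doubly_robust, balance=balance, analysis=name
        )
    except (RuntimeError, ValueError) as exc:
        logger.warning("%s: %s", name, exc)
        return AnalysisResult(name, balance=balance, weight_info=info,
                              note=f"not estimable: {exc}")
    return AnalysisResult(name, estimates, balance, info, note=note)


def run_study_analyses(
    day_table: pd.DataFrame,
    meal_table: pd.DataFrame,
    stabilized: bool = True,
    truncate: bool = True,
    always_doubly_robust: bool = False,
) -> dict[str, AnalysisResult]:
    """The four effect analyses on built day and meal-event tables.

    Day-level (``day_table``: included days with ``elevated_count_category``,
    ``daily_steps``, ``baseline_glucose``, ``duration_min``, ``tir``,
    ``mean_glucose``): (a) elevated meal count and (b) daily steps (per 1000)
    on TIR and mean glucose.  Meal-level (``meal_table``: high-agreement
    events with non-zero calories and recorded post-meal steps): (c)
    post-meal steps (per 1000) and (d) calories (per 100 kcal) on the 3-h
    glucose response and the elevated odds; IPW is skipped at the meal level
    when the treatment-covariate correlation is already under 0.1.
    """
    results: dict[str, AnalysisResult] = {}

    day = day_table.copy()
    if len(day):
        day["daily_steps_k"] = day["daily_steps"] / 1000.0
    for outcome in ("tir", "mean_glucose"):
        name = f"elevated_count_on_{outcome}"
        if not len(day):
            results[name] = AnalysisResult(name=name, note="no included days")
        else:
            task = CausalTask(
                "elevated_count_category",
                "categorical",
                ["baseline_glucose", "duration_min", "daily_steps_k"],
                outcome,
            )
            results[name] = _run_task(
                day, task, name, stabilized, truncate,
                always_doubly_robust=always_doubly_robust,
            )
        name = f"daily_steps_on_{outcome}"
        if not len(day):
            results[name] = AnalysisResult(name=name, note="no included days")
        else:
            task = CausalTask(
                "daily_steps_k",
                "continuous",
                ["baseline_glucose", "elevated_count_category", "duration_min"],
                outcome,
            )
            results[name] = _run_task(
                day, task, name, stabilized, truncate,
                always_doubly_robust=always_doubly_robust,
            )

    meal = meal_table.copy()
    if len(meal):
        meal = meal[
            meal["high_agreement"]
            & meal["calories"].notna()
            & (meal["calories"] > 0)
            & meal["post_meal_steps"].notna()
        ].reset_index(drop=True)
    if len(meal):
        meal["post_steps_k"] = meal["post_meal_steps"].astype(float) / 1000.0
        meal["calories_100"] = meal["calories"].astype(float) / 100.0
        meal["elevated"] = (meal["label"] == "elevated").astype(float)
        r = (
            abs(np.corrcoef(meal["post_steps_k"], meal["calories_100"])[0, 1])
            if meal["post_steps_k"].nunique() > 1 and meal["calories_100"].nunique() > 1
            else 0.0
        )
        skip = bool(r < CORRELATION_BALANCE_THRESHOLD)
    for treatment, covariate, tag in (
        ("post_steps_k", "calories_100", "post_meal_steps"),
        ("calories_100", "post_steps_k", "calories"),
    ):
        for outcome, otype in (("mgr_3h", "continuous"), ("elevated", "binary")):
            name = f"{tag}_on_{outcome}"
            if not len(meal):
                results[name] = AnalysisResult(name=name, note="no qualifying meal events")
                continue
            if meal[outcome].nunique() < 2:
                results[name] = AnalysisResult(name=name, note="degenerate outcome")
                continue
            task = CausalTask(treatment, "continuous", [covariate], outcome, otype)
            results[name] = _run_task(
                meal, task, name, stabilized, truncate, skip_ipw=skip,
                always_doubly_robust=always_doubly_robust,
            )
    return results


def effects_to_frame(results: dict[str, AnalysisResult]) -> pd.DataFrame:
    rows = []
    for result in results.values():
        if not result.estimable:
            rows.append(
                {
                    "analysis": result.name, "term": "", "estimate": np.nan,
                    "se": np.nan, "p_value": np.nan, "significant": False,
                    "doubly_robust": False, "balance_pass": np.nan,
                    "n": 0, "note": result.note,
                }
            )
            continue
        for est in result.estimates:
            rows.append(
                {
                    "analysis": est.analysis,
                    "term": est.term,
                    "estimate": est.estimate,
                    "se": est.se,
                    "p_value": est.p_value,
                    "significant": est.significant,
                    "doubly_robust": est.doubly_robust,
                    "balance_pass": (
                        result.balance.passed if result.balance is not None else np.nan
                    ),
                    "n": est.n,
                    "note": result.note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "analysis", "term", "estimate", "se", "p_value", "significant",
            "doubly_robust", "balance_pass", "n", "note",
        ],
    )


def balance_to_frame(results: dict[str, AnalysisResult]) -> pd.DataFrame:
    rows = []
    for result in results.values():
        if result.balance is None:
            continue
        for cov in result.balance.before:
            rows.append(
                {
                    "analysis": result.name,
                    "covariate": cov,
                    "metric": result.balance.metric,
                    "before": result.balance.before[cov],
                    "after": result.balance.after[cov],
                    "threshold": result.balance.threshold,
                    "pass": abs(result.balance.after[cov]) < result.balance.threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["analysis", "covariate", "metric", "before", "after", "threshold", "pass"],
    )
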