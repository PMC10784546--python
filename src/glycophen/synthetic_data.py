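"""Synthetic multimodal cohorts with known ground truth.

Generates CGM, step, and food-log streams with the statistical structure the
downstream analysis assumes: bell-shaped postprandial excursions on a 15-min
grid, a linear participant-level map from mean 3-h meal glucose response to
HbA1c, planted effects of calories (positive) and post-meal steps (negative)
on the meal response, realistic logging errors (missed logs, delayed logs,
end-of-day batch logging), emulated human annotators, and a separate
participant-day generator with planted treatment effects and confounding for
validating the causal estimators.

All randomness flows from a single ``numpy`` ``default_rng`` seeded by the
config, so equal seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io_schemas import (
    AnnotatedTiming,
    Bundle,
    FoodItem,
    FoodLog,
    GlucoseTrace,
    Participant,
    StepTrace,
)

_ITEM_NAMES = (
    "oatmeal", "orange juice", "tacos", "rice and beans", "chicken soup",
    "tamales", "salad", "coffee with milk", "eggs", "tortilla", "fruit cup",
    "sandwich",
)

#: nominal meal occasion centers, hours since midnight
_OCCASION_HOURS = {"breakfast": 7.5, "lunch": 12.5, "dinner": 18.5}


@dataclass
class MealResponseParams:
    """Shape of one meal's CGM excursion (truncated gamma-like bell)."""

    time_to_peak_min: float = 60.0
    shape: float = 3.0  # larger -> narrower bell

    def unit_curve(self, minutes: np.ndarray) -> np.ndarray:
        """Bell with peak 1 at ``time_to_peak_min``, zero outside [0, 180]."""
        t = np.asarray(minutes, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (t / self.time_to_peak_min) ** self.shape * np.exp(
                self.shape * (1.0 - t / self.time_to_peak_min)
            )
        u = np.where((t <= 0) | (t >= 180), 0.0, u)
        return u


@dataclass
class LoggingErrorModel:
    p_missing: float = 0.10
    delay_mean_min: float = 20.0
    p_batch_end_of_day: float = 0.05
    batch_hour: float = 21.0

    def validate(self) -> None:
        for p in (self.p_missing, self.p_batch_end_of_day):
            if not 0.0 <= p <= 1.0:
                raise ValueError("logging probabilities must be in [0, 1]")
        if self.delay_mean_min < 0:
            raise ValueError("delay mean must be >= 0")


@dataclass
class AnnotatorModel:
    jitter_sd_min: float = 5.0
    p_unknown: float = 0.02
    p_detect_added: float = 0.8

    def validate(self) -> None:
        for p in (self.p_unknown, self.p_detect_added):
            if not 0.0 <= p <= 1.0:
                raise ValueError("annotator probabilities must be in [0, 1]")
        if self.jitter_sd_min < 0:
            raise ValueError("jitter sd must be >= 0")


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; ``rng_seed`` fully determines output."""

    n_participants: int = 36
    n_days: int = 14
    cgm_interval_min: int = 15
    meal_rate_per_day: float = 3.0
    meal_time_jitter_hours: float = 0.75
    meal_response: MealResponseParams = field(default_factory=MealResponseParams)
    #: participant-level baseline meal response, min·mg/dL
    base_mgr_mean: float = 2400.0
    base_mgr_sd: float = 800.0
    #: planted effects on the 3-h response
    effect_calories_on_mgr: float = 1.83  # min·mg/dL per kcal
    effect_steps_on_mgr: float = -0.641  # min·mg/dL per step
    mgr_noise_sd: float = 0.0
    #: meal composition
    calories_log_mean: float = 6.3  # exp(6.3) ~ 545 kcal
    calories_log_sd: float = 0.35
    #: activity
    ambient_steps_per_min: float = 3.0
    walk_steps_mean: float = 800.0
    walk_steps_sd: float = 400.0
    #: dependence of post-meal walking on meal size (treatment-covariate link)
    confounding_strength: float = 0.1
    #: HbA1c map
    mapper_slope: float = 0.00065
    mapper_intercept: float = 4.4
    hba1c_noise_sd: float = 0.3
    #: CGM noise and baseline
    cgm_noise_sd: float = 0.0
    baseline_glucose_mean: float = 112.0
    baseline_glucose_sd: float = 8.0
    logging_error_model: LoggingErrorModel = field(default_factory=LoggingErrorModel)
    annotator_model: AnnotatorModel = field(default_factory=AnnotatorModel)
    study_start: str = "2022-03-01"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("cohort must have >= 1 participant and >= 1 day")
        if self.meal_rate_per_day < 0:
            raise ValueError("meal rate must be >= 0")
        if self.baseline_glucose_mean - 4 * self.baseline_glucose_sd <= 0:
            raise ValueError("config implies non-positive glucose floor")
        for sd in (self.mgr_noise_sd, self.hba1c_noise_sd, self.cgm_noise_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        self.logging_error_model.validate()
        self.annotator_model.validate()


@dataclass
class GroundTruth:
    """True meals, responses, and participant-level quantities."""

    meals: pd.DataFrame  # one row per generated meal
    participants: pd.DataFrame  # baseline, true mean MGR, HbA1c, status
    config: SimulationConfig

    def true_mean_mgr(self) -> dict[str, float]:
        return self.participants.set_index("participant_id")["true_mean_mgr"].to_dict()


def _status_from_hba1c(hba1c: float) -> str:
    if hba1c < 5.7:
        return "at_risk"
    if hba1c < 6.5:
        return "prediabetes"
    return "t2d"


def _draw_meal_times(rng: np.random.Generator, config: SimulationConfig) -> list[tuple[str, float]]:
    """One day's (occasion, hour) pairs, spaced >= 3.2 h, inside [4.2, 20.7]."""
    p_occ = min(1.0, config.meal_rate_per_day / 3.0)
    out: list[tuple[str, float]] = []
    prev = -10.0
    for occasion, center in _OCCASION_HOURS.items():
        present = rng.random() < p_occ
        hour = center + rng.normal(0.0, config.meal_time_jitter_hours)
        hour = float(np.clip(hour, 4.2, 20.7))
        if present and hour - prev >= 3.2:
            out.append((occasion, hour))
            prev = hour
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[Bundle, GroundTruth]:
    """Generate a full multimodal bundle plus its ground truth.

    CGM truth is built on a 1-min grid (flat participant baseline plus
    superposed excursion bells) and sampled to the CGM grid; each meal's true
    3-h incremental response is the 1-min Riemann sum of its bell, equal by
    construction to the planted calories/steps linear model.  The CGM sensor
    runs from noon of day 0 to noon of day ``n_days``, so the first and last
    calendar days are incomplete.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    start = pd.Timestamp(config.study_start).normalize()
    n_min = (config.n_days + 1) * 1440  # truth grid covers the trailing half day
    minutes_axis = np.arange(n_min)

    unit = config.meal_response.unit_curve(np.arange(181, dtype=float))
    unit_area_1min = float(np.sum(unit[:180]))  # left Riemann sum over [0, 180)

    bundle = Bundle()
    meal_rows: list[dict] = []
    part_rows: list[dict] = []

    for idx in range(config.n_participants):
        pid = f"P{idx + 1:03d}"
        baseline = float(
            np.clip(
                rng.normal(config.baseline_glucose_mean, config.baseline_glucose_sd),
                60.0,
                200.0,
            )
        )
        base_mgr = float(np.clip(rng.normal(config.base_mgr_mean, config.base_mgr_sd), 800.0, 5500.0))

        # ambient steps over the whole study (minute grid, days 0..n_days-1)
        day_minutes = config.n_days * 1440
        ambient = rng.poisson(config.ambient_steps_per_min, size=day_minutes)
        wear = np.zeros(day_minutes, dtype=bool)
        wear_bounds = []
        for d in range(config.n_days):
            wstart = int(round(6 * 60 + rng.normal(0, 20)))
            wend = int(round(21.5 * 60 + rng.normal(0, 20)))
            wear[d * 1440 + wstart : d * 1440 + wend] = True
            wear_bounds.append((wstart, wend))
        steps = np.where(wear, ambient, 0)

        truth_curve = np.full(n_min, baseline, dtype=float)

        # meals
        p_meals: list[dict] = []
        for d in range(config.n_days):
            for occasion, hour in _draw_meal_times(rng, config):
                # snap to the CGM grid so noise-free baselines are exact
                step = config.cgm_interval_min
                start_min = d * 1440 + int(round(hour * 60 / step)) * step
                calories = float(np.exp(rng.normal(config.calories_log_mean, config.calories_log_sd)))
                cal_z = (np.log(calories) - config.calories_log_mean) / config.calories_log_sd
                walk = float(
                    max(
                        0.0,
                        rng.normal(
                            config.walk_steps_mean - config.confounding_strength * 300.0 * cal_z,
                            config.walk_steps_sd,
                        ),
                    )
                )
                # spread the walk over minutes 10..40 post meal (within wear)
                w0, w1 = start_min + 10, start_min + 40
                if w1 <= day_minutes:
                    per_min = np.diff(np.round(np.linspace(0, walk, w1 - w0 + 1))).astype(int)
                    steps[w0:w1] += np.where(wear[w0:w1], per_min, 0)
                post_steps = int(steps[start_min : start_min + 60][wear[start_min : start_min + 60]].sum())
                target = (
                    base_mgr
                    + config.effect_calories_on_mgr * calories
                    + config.effect_steps_on_mgr * post_steps
                    + (rng.normal(0.0, config.mgr_noise_sd) if config.mgr_noise_sd else 0.0)
                )
                target = float(max(target, 250.0))
                amp = target / unit_area_1min
                seg = amp * unit
                truth_curve[start_min : start_min + 181] += seg[: n_min - start_min]
                true_mgr = float(np.sum(seg[:180]))  # 1-min Riemann sum over [0, 180)
                # the same response as the CGM-grid trapezoid the pipeline
                # measures (meal starts are grid-aligned); HbA1c is driven by
                # this so the noise-free limit is exactly recoverable
                step_off = np.arange(0, 181, config.cgm_interval_min)
                true_mgr_grid = float(np.trapezoid(seg[step_off], step_off))
                p_meals.append(
                    {
                        "participant_id": pid,
                        "day": d,
                        "occasion": occasion,
                        "true_start": start + pd.Timedelta(minutes=start_min),
                        "calories": calories,
                        "post_meal_steps": post_steps,
                        "true_mgr": true_mgr,
                        "true_mgr_grid": true_mgr_grid,
                        "peak_amplitude": amp,
                    }
                )

        # CGM sampling: 04:00 day 0 .. 04:00 day n_days on the nominal grid,
        # so every planted meal window has coverage while the first and last
        # calendar days stay incomplete (sensor insertion/removal)
        cgm_start = 4 * 60
        cgm_end = config.n_days * 1440 + 4 * 60
        cgm_idx = np.arange(cgm_start, cgm_end, config.cgm_interval_min)
        cgm_values = truth_curve[cgm_idx]
        if config.cgm_noise_sd:
            cgm_values = cgm_values + rng.normal(0.0, config.cgm_noise_sd, size=len(cgm_idx))
        cgm_values = np.maximum(cgm_values, 40.5)
        bundle.glucose[pid] = GlucoseTrace(
            pid,
            start + pd.to_timedelta(cgm_idx, unit="m"),
            cgm_values,
            nominal_interval=config.cgm_interval_min,
        )
        bundle.steps[pid] = StepTrace(
            pid,
            start + pd.to_timedelta(np.arange(day_minutes), unit="m"),
            steps,
            wear=wear,
        )

        # food logs with logging errors
        lem = config.logging_error_model
        meals_by_day: dict[int, list[dict]] = {}
        for m in p_meals:
            meals_by_day.setdefault(m["day"], []).append(m)
        for d, meals in meals_by_day.items():
            batch = rng.random() < lem.p_batch_end_of_day
            for m in meals:
                missing = rng.random() < lem.p_missing
                m["logged"] = not missing
                if missing:
                    m["log_time"] = None
                    m["log_key"] = None
                    continue
                if batch:
                    log_time = start + pd.Timedelta(minutes=d * 1440 + int(lem.batch_hour * 60))
                else:
                    delay = rng.exponential(lem.delay_mean_min) if lem.delay_mean_min else 0.0
                    log_minute = int(
                        min(
                            (m["true_start"] - start).total_seconds() / 60 + round(delay),
                            d * 1440 + 1439,
                        )
                    )
                    log_time = start + pd.Timedelta(minutes=log_minute)
                n_items = 1 + int(rng.random() < 0.4)
                split = rng.dirichlet(np.ones(n_items)) * m["calories"]
                items = [
                    FoodItem(
                        _ITEM_NAMES[int(rng.integers(len(_ITEM_NAMES)))],
                        round(float(c), 1),
                        round(float(c) * 0.5 / 4, 1),
                        round(float(c) * 0.2 / 4, 1),
                        round(float(c) * 0.3 / 9, 1),
                    )
                    for c in split
                ]
                log = FoodLog(pid, log_time, m["occasion"], items)
                bundle.food_logs.append(log)
                m["log_time"] = log_time
                m["log_key"] = log.key
        meal_rows.extend(p_meals)

        true_mean_mgr = (
            float(np.mean([m["true_mgr"] for m in p_meals])) if p_meals else 0.0
        )
        true_mean_mgr_grid = (
            float(np.mean([m["true_mgr_grid"] for m in p_meals])) if p_meals else 0.0
        )
        hba1c = (
            config.mapper_intercept
            + config.mapper_slope * true_mean_mgr_grid
            + (rng.normal(0.0, config.hba1c_noise_sd) if config.hba1c_noise_sd else 0.0)
        )
        hba1c = float(np.clip(hba1c, 3.2, 19.5))
        status = _status_from_hba1c(hba1c)
        bundle.participants.append(Participant(pid, hba1c, status))
        part_rows.append(
            {
                "participant_id": pid,
                "baseline_glucose": baseline,
                "base_mgr": base_mgr,
                "true_mean_mgr": true_mean_mgr,
                "true_mean_mgr_grid": true_mean_mgr_grid,
                "hba1c": hba1c,
                "status": status,
            }
        )

    meals_df = pd.DataFrame(
        meal_rows,
        columns=[
            "participant_id", "day", "occasion", "true_start", "calories",
            "post_meal_steps", "true_mgr", "true_mgr_grid", "peak_amplitude",
            "logged", "log_time", "log_key",
        ],
    )
    truth = GroundTruth(meals_df, pd.DataFrame(part_rows), config)
    return bundle, truth


def simulate_annotators(
    bundle: Bundle,
    ground_truth: GroundTruth,
    annotator_model: Optional[AnnotatorModel] = None,
    n_annotators: int = 4,
    rng: Optional[np.random.Generator] = None,
) -> list[AnnotatedTiming]:
    """Emulate independent annotators correcting / adding meal timings.

    Per annotator: each logged meal gets a corrected timing at the true start
    plus Normal jitter (or an unknown tag); each unlogged true meal is added
    with probability ``p_detect_added``.  The returned timings are also
    attached to ``bundle.annotations``.
    """
    if n_annotators < 1:
        raise ValueError("need at least 1 annotator")
    model = annotator_model or ground_truth.config.annotator_model
    model.validate()
    if rng is None:
        rng = np.random.default_rng(ground_truth.config.rng_seed + 1)

    annotations: list[AnnotatedTiming] = []
    meals = ground_truth.meals
    for a in range(n_annotators):
        aid = f"A{a + 1}"
        for m in meals.itertuples(index=False):
            true_start = pd.Timestamp(m.true_start)
            day_floor = true_start.normalize() + pd.Timedelta(hours=4)
            day_ceil = true_start.normalize() + pd.Timedelta(hours=23, minutes=59)

            def _jittered() -> pd.Timestamp:
                t = true_start + pd.Timedelta(
                    minutes=round(rng.normal(0.0, model.jitter_sd_min))
                )
                return min(max(t, day_floor), day_ceil)

            if m.logged:
                if rng.random() < model.p_unknown:
                    annotations.append(
                        AnnotatedTiming(m.participant_id, aid, "unknown", m.log_key, None)
                    )
                else:
                    annotations.append(
                        AnnotatedTiming(
                            m.participant_id, aid, "corrected", m.log_key, _jittered()
                        )
                    )
            elif rng.random() < model.p_detect_added:
                annotations.append(
                    AnnotatedTiming(m.participant_id, aid, "added", None, _jittered())
                )
    bundle.annotations = annotations
    return annotations


# ---------------------------------------------------------------------------
# participant-day generator for causal estimator validation


@dataclass
class DailyOutcomeConfig:
    """Planted linear model for participant-day outcomes with confounding.

    Treatments: elevated meal count category (0/1/2/>=3) and daily steps (in
    thousands).  Covariates: baseline glucose and day duration.  Outcomes
    follow a linear model with participant random intercepts; the treatments
    depend on the covariates with strength ``confounding_strength``.
    """

    n_participants: int = 36
    n_days: int = 12
    confounding_strength: float = 0.4
    #: planted treatment effects on TIR (%), categories 1, 2, >=3 vs 0, then
    #: steps per 1000
    tir_effects: tuple = (-1.0, -4.0, -8.0)
    tir_steps_effect: float = 0.5
    glucose_effects: tuple = (1.7, 5.8, 7.7)
    glucose_steps_effect: float = -0.3
    #: covariate effects (per SD of baseline glucose / duration)
    tir_baseline_effect: float = -4.0
    tir_duration_effect: float = -1.0
    glucose_baseline_effect: float = 6.0
    glucose_duration_effect: float = 1.0
    random_intercept_sd: float = 3.0
    noise_sd: float = 5.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2 or self.n_days < 1:
            raise ValueError("need >= 2 participants and >= 1 day")
        if min(self.random_intercept_sd, self.noise_sd) < 0:
            raise ValueError("sds must be >= 0")


def simulate_daily_outcome_cohort(
    config: DailyOutcomeConfig,
) -> tuple[pd.DataFrame, dict]:
    """Participant-day table with planted coefficients; returns (table, truth).

    Treatment assignment: steps and the elevated-count latent both load on
    the (standardized) covariates with weight ``confounding_strength``, so a
    naive regression of outcome on treatment alone is biased; the outcome
    model itself is exactly linear (no clipping), so a correctly adjusted
    estimator is unbiased.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_participants * config.n_days
    pid = np.repeat([f"P{i + 1:03d}" for i in range(config.n_participants)], config.n_days)
    day = np.tile(np.arange(config.n_days), config.n_participants)

    b_i = rng.normal(0.0, 6.0, config.n_participants)
    baseline = rng.normal(100.0, 10.0, n) + np.repeat(b_i, config.n_days)
    duration = rng.normal(900.0, 60.0, n)
    baseline_z = (baseline - 100.0) / 10.0
    duration_z = (duration - 900.0) / 60.0

    c = config.confounding_strength
    steps_k = 6.0 - c * 1.0 * baseline_z - c * 0.3 * duration_z + rng.normal(0.0, 1.5, n)
    steps_k = np.maximum(steps_k, 0.1)

    latent = (
        c * (0.6 * baseline_z + 0.3 * duration_z - 0.25 * (steps_k - 6.0) / 1.5)
        + rng.normal(0.0, 1.0, n)
    )
    count = np.digitize(latent, [-0.2, 0.7, 1.4])  # 0, 1, 2, 3(=">=3")

    u_tir = np.repeat(rng.normal(0.0, config.random_intercept_sd, config.n_participants), config.n_days)
    u_glu = np.repeat(rng.normal(0.0, config.random_intercept_sd, config.n_participants), config.n_days)
    cat_effect = np.array([0.0, *config.tir_effects])
    tir = (
        85.0
        + cat_effect[count]
        + config.tir_steps_effect * steps_k
        + config.tir_baseline_effect * baseline_z
        + config.tir_duration_effect * duration_z
        + u_tir
        + rng.normal(0.0, config.noise_sd, n)
    )
    gcat = np.array([0.0, *config.glucose_effects])
    glucose = (
        105.0
        + gcat[count]
        + config.glucose_steps_effect * steps_k
        + config.glucose_baseline_effect * baseline_z
        + config.glucose_duration_effect * duration_z
        + u_glu
        + rng.normal(0.0, config.noise_sd, n)
    )

    table = pd.DataFrame(
        {
            "participant_id": pid,
            "day": day,
            "baseline_glucose": baseline,
            "duration": duration,
            "daily_steps_k": steps_k,
            "elevated_count": count,
            "tir": tir,
            "mean_glucose": glucose,
        }
    )
    truth = {
        "tir": {
            "count_1": config.tir_effects[0],
            "count_2": config.tir_effects[1],
            "count_3plus": config.tir_effects[2],
            "steps_per_1000": config.tir_steps_effect,
        },
        "mean_glucose": {
            "count_1": config.glucose_effects[0],
            "count_2": config.glucose_effects[1],
            "count_3plus": config.glucose_effects[2],
            "steps_per_1000": config.glucose_steps_effect,
        },
    }
    return table, truth


def ground_truth_to_csv(truth: GroundTruth, path) -> None:
    df = truth.meals.copy()
    df["true_start"] = pd.to_datetime(df["true_start"]).dt.strftime("%Y-%m-%dT%H:%M")
    df["log_time"] = pd.to_datetime(df["log_time"]).dt.strftime("%Y-%m-%dT%H:%M")
    df.to_csv(path, index=False)


def config_from_dict(payload: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (possibly nested) plain dict."""
    payload = dict(payload)
    kwargs = {}
    if "meal_response" in payload:
        kwargs["meal_response"] = MealResponseParams(**payload.pop("meal_response"))
    if "logging_error_model" in payload:
        kwargs["logging_error_model"] = LoggingErrorModel(**payload.pop("logging_error_model"))
    if "annotator_model" in payload:
        kwargs["annotator_model"] = AnnotatorModel(**payload.pop("annotator_model"))
    kwargs.update(payload)
    return SimulationConfig(**kwargs)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
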