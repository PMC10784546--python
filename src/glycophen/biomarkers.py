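"""Meal-event biomarkers and the elevated/normal classification.

The central quantity is the 3-h meal glucose response (``mgr_3h``): the
incremental area under the post-meal CGM curve — baseline-subtracted,
negative-clipped, trapezoid-integrated over minutes — in min·mg/dL.  A
cohort-level robust (Huber) regression maps each participant's mean response
to HbA1c; individual events are then classified *elevated* when their mapped
hypothetical HbA1c reaches the status-specific threshold (5.7% for at-risk /
prediabetes participants, 6.5% for T2D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_schemas import StepTrace

#: classification thresholds in HbA1c percent, by diabetes status group
THRESHOLDS = {"non_t2d": 5.7, "t2d": 6.5}

POST_MEAL_WINDOW_MIN = 60
SEGMENT_DURATION_MIN = 180


def mgr_3h(minutes: np.ndarray, values: np.ndarray, baseline: float) -> float:
    """Incremental AUC of a post-meal CGM segment, in min·mg/dL.

    Parameters
    ----------
    minutes : offsets from the meal start in minutes, increasing, within
        [0, 180].
    values : glucose samples (mg/dL) at those offsets.
    baseline : glucose at the meal start time.

    The baseline is subtracted, negative excursions are clipped to zero, and
    the trapezoidal rule integrates over minutes.  No zero-crossing
    refinement is applied: the clipped curve is integrated on the sample
    grid as-is, so the result can differ from the continuous-time integral
    by at most one sample width around each baseline crossing.
    """
    minutes = np.asarray(minutes, dtype=float)
    values = np.asarray(values, dtype=float)
    if minutes.shape != values.shape:
        raise ValueError("minutes and values must have the same shape")
    if minutes.size < 2:
        raise ValueError("mgr_3h needs at least 2 samples")
    if np.any(np.diff(minutes) <= 0):
        raise ValueError("minutes must be strictly increasing")
    if minutes[0] < 0 or minutes[-1] > SEGMENT_DURATION_MIN:
        raise ValueError("segment must lie within [0, 180] minutes")
    incremental = np.clip(values - baseline, 0.0, None)
    return float(np.trapezoid(incremental, minutes))


def post_meal_steps(step_trace: StepTrace, start_time: pd.Timestamp) -> Optional[int]:
    """Steps in the 1-h half-open window after the meal start.

    Returns ``None`` when the watch records no wear minutes in the window —
    absence of a measurement, not zero activity.
    """
    start = pd.Timestamp(start_time)
    end = start + pd.Timedelta(minutes=POST_MEAL_WINDOW_MIN)
    if step_trace.wear_minutes_between(start, end) == 0:
        return None
    return step_trace.steps_between(start, end)


@dataclass
class HbA1cMapper:
    """Fitted map f from mean 3-h meal glucose response to HbA1c.

    ``coefficients`` are polynomial coefficients in increasing degree order
    (intercept first).  ``sigma`` is the robust residual scale of the fit.
    """

    coefficients: np.ndarray
    sigma: float
    thresholds: dict = field(default_factory=lambda: dict(THRESHOLDS))
    diagnostics: dict = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    def predict(self, mean_mgr: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(mean_mgr, dtype=float)
        out = np.zeros_like(x)
        for d, c in enumerate(self.coefficients):
            out = out + c * x**d
        return float(out) if np.isscalar(mean_mgr) else out

    def is_monotone_nondecreasing(self, lo: float, hi: float) -> bool:
        grid = np.linspace(lo, hi, 512)
        return bool(np.all(np.diff(self.predict(grid)) >= -1e-12))

    def to_json(self) -> str:
        payload = {
            "coefficients": list(map(float, self.coefficients)),
            "slope": self.slope,
            "intercept": self.intercept,
            "sigma": self.sigma,
            "thresholds": self.thresholds,
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if not isinstance(v, pd.DataFrame)
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HbA1cMapper":
        payload = json.loads(text)
        return cls(
            np.asarray(payload["coefficients"], dtype=float),
            float(payload["sigma"]),
            payload.get("thresholds", dict(THRESHOLDS)),
            payload.get("diagnostics", {}),
        )


def fit_hba1c_mapper(
    mean_mgr_by_participant: dict[str, float],
    hba1c_by_participant: dict[str, float],
    degree: int = 1,
    huber_t: float = 1.345,
) -> HbA1cMapper:
    """Robust (Huber M-estimated) regression of HbA1c on mean MGR_3h.

    ``degree`` 1 fits a line, 2 adds a quadratic term (sensitivity analysis).
    Diagnostics include Pearson r and MAE between true and fitted HbA1c,
    overall and excluding participants with HbA1c > 10.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    common = sorted(set(mean_mgr_by_participant) & set(hba1c_by_participant))
    if len(common) < 3:
        raise ValueError("need at least 3 participants with meal events to fit mapper")
    x = np.array([mean_mgr_by_participant[p] for p in common], dtype=float)
    y = np.array([hba1c_by_participant[p] for p in common], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: mean MGR_3h has zero variance")

    exog = np.column_stack([x**d for d in range(degree + 1)])
    fit = sm.RLM(y, exog, M=sm.robust.norms.HuberT(t=huber_t)).fit()
    coefficients = np.asarray(fit.params, dtype=float)
    fitted = exog @ coefficients
    sigma = float(fit.scale)

    diagnostics = _fit_diagnostics(common, x, y, fitted)
    mapper = HbA1cMapper(coefficients, sigma, dict(THRESHOLDS), diagnostics)
    mapper.diagnostics["monotone"] = mapper.is_monotone_nondecreasing(x.min(), x.max())
    return mapper


def _fit_diagnostics(pids, x, y, fitted) -> dict:
    def _stats(mask: np.ndarray) -> dict:
        yy, ff = y[mask], fitted[mask]
        if len(yy) < 2 or np.std(yy) == 0 or np.std(ff) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(yy, ff)[0, 1])
        return {"pearson_r": r, "mae": float(np.mean(np.abs(yy - ff))), "n": int(mask.sum())}

    all_mask = np.ones(len(y), bool)
    return {
        "participants": list(pids),
        "mean_mgr": list(map(float, x)),
        "hba1c_true": list(map(float, y)),
        "hba1c_fitted": list(map(float, fitted)),
        "overall": _stats(all_mask),
        "excluding_high_hba1c": _stats(y <= 10.0),
    }


def classify_event(
    mgr_3h_value: float, mapper: HbA1cMapper, status: str
) -> tuple[str, float]:
    """Classify one meal event as ``('elevated'|'normal', mapped_hba1c)``.

    The event's response is pushed through the cohort map f as if it were the
    participant's average; the threshold is 5.7% for at-risk/prediabetes and
    6.5% for T2D, inclusive at the boundary.
    """
    if mapper is None:
        raise ValueError("mapper must be fitted before classification")
    mapped = float(mapper.predict(float(mgr_3h_value)))
    threshold = mapper.thresholds["t2d" if status == "t2d" else "non_t2d"]
    return ("elevated" if mapped >= threshold else "normal"), mapped


def compute_event_biomarkers(
    events,
    step_traces: dict[str, StepTrace],
    food_log_by_key: dict,
    mapper: HbA1cMapper,
    status_by_participant: dict[str, str],
) -> pd.DataFrame:
    """Biomarker table for qualified meal events.

    One row per event: mgr_3h, post_meal_steps (nullable), calories
    (nullable, from the linked merged log), mapped_hba1c, and label.
    """
    rows = []
    for ev in events:
        value = mgr_3h(ev.segment_minutes, ev.segment_values, ev.baseline_glucose)
        trace = step_traces.get(ev.participant_id)
        steps = post_meal_steps(trace, ev.start_time) if trace is not None else None
        calories = None
        if ev.linked_log is not None:
            calories = ev.linked_log.total_calories
        label, mapped = classify_event(
            value, mapper, status_by_participant[ev.participant_id]
        )
        rows.append(
            {
                "participant_id": ev.participant_id,
                "start_time": ev.start_time,
                "mgr_3h": value,
                "post_meal_steps": steps,
                "calories": calories,
                "mapped_hba1c": mapped,
                "label": label,
                "high_agreement": ev.high_agreement,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "start_time",
            "mgr_3h",
            "post_meal_steps",
            "calories",
            "mapped_hba1c",
            "label",
            "high_agreement",
        ],
    )
    return df


def mean_mgr_by_participant(biomarker_table: pd.DataFrame) -> dict[str, float]:
    """Per-participant mean of mgr_3h over their qualified meal events."""
    return biomarker_table.groupby("participant_id")["mgr_3h"].mean().to_dict()
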