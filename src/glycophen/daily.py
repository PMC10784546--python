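"""Participant-day records: analysis windows, daily biomarkers, inclusion rules.

A day's analysis window starts at the earlier of the first meal event and the
first detected wear time after 04:00, and ends at the later of (last meal
start + 3 h) and the last wear time before 23:59, clipped to [04:00, 23:59].
Days are excluded (with a recorded reason, never an error) when no meals were
identified, wear time in 04:00-23:59 is under 10 h, the day's CGM record is
incomplete (notably the first and last study days), or any CGM sample sits at
the sensor limits (<= 40 or >= 500 mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_schemas import Bundle, StepTrace
from .meal_events import MealEvent, merge_food_logs

DAY_START_H = 4
DAY_END = pd.Timedelta(hours=23, minutes=59)
MIN_WEAR_MINUTES = 600  # >= 10 h, inclusive
SENSOR_LOW, SENSOR_HIGH = 40.0, 500.0
NONWEAR_RUN_MIN = 90  # zero-step run length marking non-wear when no mask
ADHERENCE_MIN_DAYS = 10
FEASIBILITY_FRACTION = 0.5


@dataclass
class DayRecord:
    participant_id: str
    date: object
    window_start: Optional[pd.Timestamp]
    window_end: Optional[pd.Timestamp]
    duration_min: float
    elevated_count: int
    elevated_count_category: int  # 0, 1, 2, 3 (3 means ">=3")
    daily_steps: int
    baseline_glucose: float
    tir: float
    mean_glucose: float
    included: bool
    exclusion_reason: str = ""


def wear_spans(trace: StepTrace, date) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Contiguous wear spans (half-open) for one calendar day.

    Uses the explicit wear mask when present; otherwise a simplified
    surrogate for the Choi algorithm: runs of >= 90 consecutive zero-step
    minutes count as non-wear.
    """
    day0 = pd.Timestamp(date)
    day1 = day0 + pd.Timedelta(days=1)
    mask = (trace.times >= day0) & (trace.times < day1)
    if not mask.any():
        return []
    times = trace.times[mask]
    if trace.wear is not None:
        wear = trace.wear[mask]
    else:
        steps = trace.steps[mask]
        wear = np.ones(len(steps), dtype=bool)
        run_start = None
        for i, s in enumerate(list(steps) + [1]):  # sentinel flushes last run
            if s == 0 and run_start is None:
                run_start = i
            elif s != 0 and run_start is not None:
                if i - run_start >= NONWEAR_RUN_MIN:
                    wear[run_start:i] = False
                run_start = None
    spans: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    start_idx = None
    for i, w in enumerate(list(wear) + [False]):
        if w and start_idx is None:
            start_idx = i
        elif not w and start_idx is not None:
            end_t = (
                times[i - 1] + pd.Timedelta(minutes=1)
                if i - 1 < len(times)
                else times[-1] + pd.Timedelta(minutes=1)
            )
            spans.append((times[start_idx], end_t))
            start_idx = None
    return spans


def day_window(
    meal_starts: Sequence[pd.Timestamp],
    wear_spans_of_day: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    date,
) -> Optional[tuple[pd.Timestamp, pd.Timestamp]]:
    """Analysis window for one day, or None when neither meals nor wear exist.

    Start: min(first meal, first wear time after 04:00); end: max(last meal
    + 3 h, last wear time before 23:59); both clipped to [04:00, 23:59].
    """
    day0 = pd.Timestamp(date)
    floor = day0 + pd.Timedelta(hours=DAY_START_H)
    ceil = day0 + DAY_END

    start_candidates: list[pd.Timestamp] = []
    end_candidates: list[pd.Timestamp] = []
    if meal_starts:
        start_candidates.append(min(meal_starts))
        end_candidates.append(max(meal_starts) + pd.Timedelta(hours=3))
    wear_after_4 = [max(s, floor) for s, e in wear_spans_of_day if e > floor]
    wear_before_end = [min(e, ceil) for s, e in wear_spans_of_day if s < ceil]
    if wear_after_4:
        start_candidates.append(min(wear_after_4))
    if wear_before_end:
        end_candidates.append(max(wear_before_end))
    if not start_candidates or not end_candidates:
        return None
    start = max(min(start_candidates), floor)
    end = min(max(end_candidates), ceil)
    if end <= start:
        return None
    return start, end


def _cgm_day_complete(trace, date) -> bool:
    """True when the day holds every expected sample at the nominal interval."""
    day0 = pd.Timestamp(date)
    day1 = day0 + pd.Timedelta(days=1)
    n = int(((trace.times >= day0) & (trace.times < day1)).sum())
    return n >= 1440 // trace.nominal_interval


def build_day_records(
    bundle: Bundle,
    events: Sequence[MealEvent],
    biomarker_table: pd.DataFrame,
    tir_lower: float = 54.0,
    tir_upper: float = 140.0,
) -> list[DayRecord]:
    """One record per participant-day spanned by the CGM trace.

    Excluded days carry their (possibly multiple, ';'-joined) reasons and NaN
    metrics where undefined; exclusions are data, not errors.
    """
    labels = {}
    if len(biomarker_table):
        labels = {
            (r.participant_id, pd.Timestamp(r.start_time)): r.label
            for r in biomarker_table.itertuples(index=False)
        }
    events_by_pid_date: dict[tuple, list[MealEvent]] = {}
    for ev in events:
        events_by_pid_date.setdefault((ev.participant_id, ev.date), []).append(ev)

    records: list[DayRecord] = []
    for pid in sorted(bundle.glucose):
        trace = bundle.glucose[pid]
        if not len(trace):
            continue
        steps_trace = bundle.steps.get(pid)
        dates = pd.date_range(trace.times[0].normalize(), trace.times[-1].normalize())
        for day0 in dates:
            date = day0.date()
            day1 = day0 + pd.Timedelta(days=1)
            day_events = sorted(
                events_by_pid_date.get((pid, date), []), key=lambda e: e.start_time
            )
            reasons = []
            if not day_events:
                reasons.append("no-meals")
            spans = wear_spans(steps_trace, date) if steps_trace is not None else []
            floor = day0 + pd.Timedelta(hours=DAY_START_H)
            ceil = day0 + DAY_END
            wear_min = sum(
                (min(e, ceil) - max(s, floor)).total_seconds() / 60
                for s, e in spans
                if e > floor and s < ceil
            )
            if wear_min < MIN_WEAR_MINUTES:
                reasons.append("wear<10h")
            if not _cgm_day_complete(trace, date):
                reasons.append("cgm-incomplete")
            day_mask = (trace.times >= day0) & (trace.times < day1)
            day_values = trace.values[day_mask]
            if len(day_values) and (
                np.any(day_values <= SENSOR_LOW) or np.any(day_values >= SENSOR_HIGH)
            ):
                reasons.append("sensor-limit")

            window = day_window([e.start_time for e in day_events], spans, date)
            if window is None:
                if "no-meals" not in reasons:
                    reasons.append("no-window")
                records.append(
                    DayRecord(pid, date, None, None, float("nan"), 0, 0, 0,
                              float("nan"), float("nan"), float("nan"), False,
                              ";".join(reasons)))
                continue
            wstart, wend = window
            duration = (wend - wstart).total_seconds() / 60.0
            in_window = [e for e in day_events if wstart <= e.start_time <= wend]
            elevated = sum(
                1
                for e in in_window
                if labels.get((pid, pd.Timestamp(e.start_time))) == "elevated"
            )
            daily_steps = (
                steps_trace.steps_between(wstart, wend) if steps_trace is not None else 0
            )
            baseline = trace.value_at(wstart)
            smask = (trace.times >= wstart) & (trace.times <= wend)
            values = trace.values[smask]
            if len(values):
                tir = 100.0 * float(np.mean((values >= tir_lower) & (values <= tir_upper)))
                mean_glucose = float(np.mean(values))
            else:
                tir = float("nan")
                mean_glucose = float("nan")
            records.append(
                DayRecord(
                    participant_id=pid,
                    date=date,
                    window_start=wstart,
                    window_end=wend,
                    duration_min=duration,
                    elevated_count=elevated,
                    elevated_count_category=min(elevated, 3),
                    daily_steps=daily_steps,
                    baseline_glucose=baseline,
                    tir=tir,
                    mean_glucose=mean_glucose,
                    included=not reasons,
                    exclusion_reason=";".join(reasons),
                )
            )
    return records


def day_records_to_frame(records: Sequence[DayRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "participant_id", "date", "window_start", "window_end",
                "duration_min", "elevated_count", "elevated_count_category",
                "daily_steps", "baseline_glucose", "tir", "mean_glucose",
                "included", "exclusion_reason",
            ]
        )
    return df


def included_day_table(records: Sequence[DayRecord]) -> pd.DataFrame:
    """Analysis table of included days (duration in minutes, steps in counts)."""
    df = day_records_to_frame(records)
    if df.empty:
        return df
    return df[df["included"]].reset_index(drop=True)


def adherence_summary(bundle: Bundle) -> tuple[pd.DataFrame, dict]:
    """Per-participant adherence day counts and cohort feasibility flags.

    MFP adherence: days with >= 2 merged meal logs.  CGM adherence: days with
    no missing samples.  ActiGraph adherence: days with >= 10 h of wear.
    Simultaneous: all three on the same day.  Cohort feasibility: more than
    half the participants with >= 10 simultaneous days.
    """
    if not bundle.participants and not bundle.glucose:
        raise ValueError("empty cohort: adherence undefined")
    merged = merge_food_logs(bundle.food_logs)
    logs_by_pid_date: dict[tuple, int] = {}
    for m in merged:
        key = (m.participant_id, m.merged_time.date())
        logs_by_pid_date[key] = logs_by_pid_date.get(key, 0) + 1

    pids = bundle.participant_ids() or sorted(bundle.glucose)
    rows = []
    for pid in pids:
        trace = bundle.glucose.get(pid)
        steps_trace = bundle.steps.get(pid)
        dates: set = set()
        if trace is not None and len(trace):
            dates.update(pd.date_range(trace.times[0].normalize(), trace.times[-1].normalize()).date)
        if steps_trace is not None and len(steps_trace):
            dates.update(
                pd.date_range(
                    steps_trace.times[0].normalize(), steps_trace.times[-1].normalize()
                ).date
            )
        mfp = cgm = act = sim = 0
        for date in sorted(dates):
            ok_mfp = logs_by_pid_date.get((pid, date), 0) >= 2
            ok_cgm = trace is not None and len(trace) and _cgm_day_complete(trace, date)
            ok_act = False
            if steps_trace is not None and len(steps_trace):
                day0 = pd.Timestamp(date)
                total_wear = sum(
                    (e - s).total_seconds() / 60
                    for s, e in wear_spans(steps_trace, date)
                )
                ok_act = total_wear >= MIN_WEAR_MINUTES
            mfp += ok_mfp
            cgm += bool(ok_cgm)
            act += ok_act
            sim += ok_mfp and ok_cgm and ok_act
        rows.append(
            {
                "participant_id": pid,
                "mfp_days": mfp,
                "cgm_days": cgm,
                "actigraph_days": act,
                "simultaneous_days": sim,
            }
        )
    per_participant = pd.DataFrame(rows)
    n = len(per_participant)
    cohort = {
        "n_participants": n,
        "frac_mfp_adherent": float((per_participant["mfp_days"] >= ADHERENCE_MIN_DAYS).mean()),
        "frac_cgm_adherent": float((per_participant["cgm_days"] >= ADHERENCE_MIN_DAYS).mean()),
        "frac_actigraph_adherent": float(
            (per_participant["actigraph_days"] >= ADHERENCE_MIN_DAYS).mean()
        ),
        "frac_simultaneous_adherent": float(
            (per_participant["simultaneous_days"] >= ADHERENCE_MIN_DAYS).mean()
        ),
    }
    cohort["feasible"] = cohort["frac_simultaneous_adherent"] >= FEASIBILITY_FRACTION
    return per_participant, cohort
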