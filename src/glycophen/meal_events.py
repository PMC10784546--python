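"""Meal-event segmentation from food logs, annotator timings, and CGM.

Stages: (1) merge staged food logs of the same occasion within 60 min into
single meal logs; (2) per participant-day, aggregate the timings from
multiple annotators with 1-D DBSCAN (eps = 1.5 h, min_samples = 2), dropping
noise points; (3) within each group, pick the member timing whose 3-h CGM
window has the largest incremental AUC; (4) qualify groups whose segment
shows a maximum glucose rise >= 18.6 mg/dL from the start-time baseline and
whose start lies in [04:00, 23:59].  Inter-annotator agreement is summarized
with ICC(2,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .biomarkers import SEGMENT_DURATION_MIN, mgr_3h
from .io_schemas import AnnotatedTiming, Bundle, FoodLog, GlucoseTrace

logger = logging.getLogger(__name__)

MERGE_WINDOW_MIN = 60
RISE_THRESHOLD_MGDL = 18.6
DAY_START = pd.Timedelta(hours=4)
DAY_END = pd.Timedelta(hours=23, minutes=59)
#: fraction of expected CGM samples a 3-h window needs for its iAUC to count
MIN_COVERAGE_FRACTION = 0.5


@dataclass
class MergedMealLog:
    """Food logs of one occasion merged within the 60-min window.

    The merged timing is the first constituent log's timing.
    """

    participant_id: str
    occasion: str
    merged_time: pd.Timestamp
    total_calories: float
    constituent_log_keys: list[str] = field(default_factory=list)

    @property
    def key(self) -> str:
        return self.constituent_log_keys[0]


@dataclass
class MealEvent:
    """A qualified meal event with its 3-h CGM segment and provenance."""

    participant_id: str
    start_time: pd.Timestamp
    segment_minutes: np.ndarray
    segment_values: np.ndarray
    baseline_glucose: float
    max_rise: float
    supporting_annotations: list[AnnotatedTiming] = field(default_factory=list)
    linked_log: Optional[MergedMealLog] = None
    high_agreement: bool = False

    @property
    def date(self):
        return self.start_time.date()


def merge_food_logs(food_logs: Sequence[FoodLog]) -> list[MergedMealLog]:
    """Greedy forward merge of staged logs, per participant per occasion.

    A log joins the open group when it is within 60 min of the group's
    *first* log (first-anchor rule), else it starts a new group.  The group
    timing is the first log's timing.
    """
    by_stream: dict[tuple[str, str], list[FoodLog]] = {}
    for log in food_logs:
        by_stream.setdefault((log.participant_id, log.occasion), []).append(log)

    merged: list[MergedMealLog] = []
    for (pid, occasion), logs in by_stream.items():
        logs = sorted(logs, key=lambda g: g.log_time)
        group: list[FoodLog] = []
        for log in logs:
            if group and (log.log_time - group[0].log_time) <= pd.Timedelta(
                minutes=MERGE_WINDOW_MIN
            ):
                group.append(log)
            else:
                if group:
                    merged.append(_finish_group(pid, occasion, group))
                group = [log]
        if group:
            merged.append(_finish_group(pid, occasion, group))
    merged.sort(key=lambda m: (m.participant_id, m.merged_time, m.occasion))
    return merged


def _finish_group(pid: str, occasion: str, group: list[FoodLog]) -> MergedMealLog:
    return MergedMealLog(
        participant_id=pid,
        occasion=occasion,
        merged_time=group[0].log_time,
        total_calories=float(sum(g.total_calories for g in group)),
        constituent_log_keys=[g.key for g in group],
    )


def aggregate_annotations(
    timings: Sequence[AnnotatedTiming],
    eps_hours: float = 1.5,
    min_samples: int = 2,
) -> list[list[AnnotatedTiming]]:
    """Cluster one participant-day's annotated timings with 1-D DBSCAN.

    Distance is absolute difference in hours since midnight.  Clusters with
    fewer than ``min_samples`` members never form; DBSCAN noise points are
    discarded.  Unknown-tagged (timeless) entries must be excluded upstream.
    Output is ordered by earliest member and independent of input order.
    """
    timed = sorted(
        (t for t in timings if t.time is not None), key=lambda t: (t.time, t.annotator_id)
    )
    if not timed:
        return []
    hours = np.array(
        [
            (t.time - t.time.normalize()).total_seconds() / 3600.0
            for t in timed
        ]
    ).reshape(-1, 1)
    labels = DBSCAN(eps=eps_hours, min_samples=min_samples).fit_predict(hours)
    groups: dict[int, list[AnnotatedTiming]] = {}
    for timing, label in zip(timed, labels):
        if label == -1:
            continue
        groups.setdefault(int(label), []).append(timing)
    return sorted(groups.values(), key=lambda g: min(t.time for t in g))


def select_start_time(
    group: Sequence[AnnotatedTiming], glucose_trace: GlucoseTrace
) -> Optional[pd.Timestamp]:
    """The member timing maximizing the 3-h incremental AUC; ties -> earliest.

    A candidate only competes when its window holds at least half of the
    expected CGM samples; returns ``None`` (group discarded) when no member
    has adequate coverage.
    """
    if not group:
        raise ValueError("empty annotation group")
    expected = SEGMENT_DURATION_MIN // glucose_trace.nominal_interval + 1
    best_time: Optional[pd.Timestamp] = None
    best_iauc = -np.inf
    for timing in sorted(group, key=lambda t: t.time):
        minutes, values = glucose_trace.segment(timing.time, SEGMENT_DURATION_MIN)
        if len(values) < max(2, MIN_COVERAGE_FRACTION * expected):
            continue
        baseline = glucose_trace.value_at(timing.time)
        if np.isnan(baseline):
            continue
        iauc = mgr_3h(minutes, values, baseline)
        if iauc > best_iauc:  # strict: earliest wins ties
            best_iauc = iauc
            best_time = timing.time
    if best_time is None:
        logger.info(
            "annotation group for %s discarded: no member has CGM coverage",
            group[0].participant_id,
        )
    return best_time


def qualify_events(
    groups: Sequence[Sequence[AnnotatedTiming]],
    glucose_trace: GlucoseTrace,
    merged_logs: Sequence[MergedMealLog],
    rise_threshold: float = RISE_THRESHOLD_MGDL,
    n_annotators: int = 4,
) -> list[MealEvent]:
    """Qualify annotation groups into meal events.

    A group qualifies when its selected start time lies in [04:00, 23:59]
    and the 3-h segment's maximum rise above the start baseline is at least
    ``rise_threshold`` (inclusive).  The event links to the merged log whose
    corrected timings dominate the group (majority; ties unlinked), and is
    high-agreement when >= 3 of the annotators' corrected timings for that
    log sit in the group.
    """
    log_key_to_merged = {
        key: m for m in merged_logs for key in m.constituent_log_keys
    }
    events: list[MealEvent] = []
    for group in groups:
        start = select_start_time(group, glucose_trace)
        if start is None:
            continue
        time_of_day = start - start.normalize()
        if not (DAY_START <= time_of_day <= DAY_END):
            continue
        baseline = glucose_trace.value_at(start)
        minutes, values = glucose_trace.segment(start, SEGMENT_DURATION_MIN)
        max_rise = float(values.max() - baseline)
        if max_rise < rise_threshold - 1e-9:  # inclusive under float noise
            continue

        linked = _majority_linked_log(group, log_key_to_merged)
        high_agreement = False
        if linked is not None:
            annotators = {
                t.annotator_id
                for t in group
                if t.source == "corrected"
                and log_key_to_merged.get(t.log_key) is linked
            }
            high_agreement = len(annotators) >= min(3, n_annotators)
        events.append(
            MealEvent(
                participant_id=glucose_trace.participant_id,
                start_time=start,
                segment_minutes=minutes,
                segment_values=values,
                baseline_glucose=baseline,
                max_rise=max_rise,
                supporting_annotations=list(group),
                linked_log=linked,
                high_agreement=high_agreement,
            )
        )
    return events


def _majority_linked_log(
    group: Sequence[AnnotatedTiming], log_key_to_merged: dict
) -> Optional[MergedMealLog]:
    votes: dict[str, int] = {}
    candidates: dict[str, MergedMealLog] = {}
    for t in group:
        if t.source != "corrected" or t.log_key is None:
            continue
        merged = log_key_to_merged.get(t.log_key)
        if merged is None:
            continue
        votes[merged.key] = votes.get(merged.key, 0) + 1
        candidates[merged.key] = merged
    if not votes:
        return None
    top = max(votes.values())
    winners = [k for k, v in votes.items() if v == top]
    if len(winners) > 1:
        return None
    return candidates[winners[0]]


def segment_meal_events(
    bundle: Bundle,
    eps_hours: float = 1.5,
    min_samples: int = 2,
    rise_threshold: float = RISE_THRESHOLD_MGDL,
) -> list[MealEvent]:
    """Full segmentation pipeline over a bundle: merge, cluster, qualify."""
    merged_logs = merge_food_logs(bundle.food_logs)
    merged_by_pid: dict[str, list[MergedMealLog]] = {}
    for m in merged_logs:
        merged_by_pid.setdefault(m.participant_id, []).append(m)

    per_day: dict[tuple[str, object], list[AnnotatedTiming]] = {}
    for timing in bundle.annotations:
        if timing.time is None:
            continue
        per_day.setdefault((timing.participant_id, timing.time.date()), []).append(timing)

    n_annotators = len({t.annotator_id for t in bundle.annotations}) or 4
    events: list[MealEvent] = []
    for (pid, _day), timings in sorted(per_day.items()):
        trace = bundle.glucose.get(pid)
        if trace is None or not len(trace):
            continue
        groups = aggregate_annotations(timings, eps_hours, min_samples)
        events.extend(
            qualify_events(
                groups,
                trace,
                merged_by_pid.get(pid, []),
                rise_threshold,
                n_annotators=n_annotators,
            )
        )
    events.sort(key=lambda e: (e.participant_id, e.start_time))
    return events


def events_to_frame(events: Sequence[MealEvent]) -> pd.DataFrame:
    """Flat table view of qualified events (one row per event)."""
    return pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "start_time": e.start_time,
                "baseline_glucose": e.baseline_glucose,
                "max_rise": e.max_rise,
                "linked_log_key": e.linked_log.key if e.linked_log else "",
                "high_agreement": e.high_agreement,
            }
            for e in events
        ],
        columns=[
            "participant_id",
            "start_time",
            "baseline_glucose",
            "max_rise",
            "linked_log_key",
            "high_agreement",
        ],
    )


def intraclass_correlation(matrix: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is logs x annotators with complete cases only (one numeric
    timing per cell, e.g. hours).  Computed from the two-way ANOVA mean
    squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ICC needs >= 2 logs and >= 2 annotators")
    if np.isnan(m).any():
        raise ValueError("ICC input must be complete cases (no NaN)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)
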