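"""On-disk tabular schemas and validated readers/writers for all data streams.

A *bundle* is a directory of five CSV files (comma-separated, header row,
UTF-8), all timestamps timezone-naive local clock time at minute precision
(ISO-8601 ``YYYY-MM-DDTHH:MM``):

- ``glucose.csv`` — ``participant_id,time,glucose_mgdl``
- ``steps.csv`` — ``participant_id,time,steps[,wear]``
- ``food_logs.csv`` — ``participant_id,log_time,occasion,item_name,calories,
  carbs_g,protein_g,fat_g`` (one row per food item)
- ``annotations.csv`` — ``participant_id,annotator_id,source,log_key,time``
- ``participants.csv`` — ``participant_id,hba1c,status``

CGM gaps are absent rows, never sentinel values; no imputation happens at
this layer.  Rows failing type or invariant checks are rejected with
row-level diagnostics (logged, returned on the bundle) — never silently
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCCASIONS = ("breakfast", "lunch", "dinner", "snacks")
STATUSES = ("at_risk", "prediabetes", "t2d")
ANNOTATION_SOURCES = ("corrected", "added", "unknown")

TIME_FORMAT = "%Y-%m-%dT%H:%M"

REQUIRED_FILES = (
    "glucose.csv",
    "steps.csv",
    "food_logs.csv",
    "annotations.csv",
    "participants.csv",
)


class BundleError(RuntimeError):
    """Fatal bundle-level problem (missing file, unwritable path, ...)."""


@dataclass
class RowIssue:
    """Diagnostic for a single rejected row."""

    file: str
    line: int  # 1-based line number in the CSV (header = line 1)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.file}:{self.line}: {self.message}"


def _require_naive(ts: pd.Timestamp, context: str) -> pd.Timestamp:
    if ts.tzinfo is not None:
        raise ValueError(f"{context}: timestamps must be timezone-naive, got {ts}")
    return ts


@dataclass
class GlucoseTrace:
    """One participant's CGM series on a (possibly gappy) minute-resolution grid.

    ``times`` are strictly increasing; ``values`` are glucose in mg/dL
    (all > 0); missing samples are absent rows. ``nominal_interval`` is the
    sensor's sampling interval in minutes.
    """

    participant_id: str
    times: pd.DatetimeIndex
    values: np.ndarray
    nominal_interval: int = 15

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) and self.times.tz is not None:
            raise ValueError("GlucoseTrace times must be timezone-naive")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("GlucoseTrace times must be increasing")
        if len(self.times) > 1 and self.times.has_duplicates:
            raise ValueError("GlucoseTrace times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("glucose values must be > 0")

    def __len__(self) -> int:
        return len(self.times)

    def segment(
        self, start: pd.Timestamp, duration_min: int = 180
    ) -> tuple[np.ndarray, np.ndarray]:
        """Samples in ``[start, start + duration_min]`` as (minute offsets, values)."""
        start = pd.Timestamp(start)
        end = start + pd.Timedelta(minutes=duration_min)
        mask = (self.times >= start) & (self.times <= end)
        offsets = (
            (self.times[mask] - start).total_seconds().to_numpy() / 60.0
        )
        return offsets, self.values[mask]

    def value_at(
        self, when: pd.Timestamp, tolerance_min: Optional[int] = None
    ) -> float:
        """Glucose at ``when``: the nearest sample within ``tolerance_min``
        (default: one nominal interval); NaN when no sample is close enough."""
        if tolerance_min is None:
            tolerance_min = self.nominal_interval
        if not len(self.times):
            return float("nan")
        when = pd.Timestamp(when)
        idx = self.times.get_indexer([when], method="nearest")[0]
        if abs((self.times[idx] - when).total_seconds()) / 60.0 <= tolerance_min:
            return float(self.values[idx])
        return float("nan")


@dataclass
class StepTrace:
    """Per-minute step counts for one participant, with optional wear mask."""

    participant_id: str
    times: pd.DatetimeIndex
    steps: np.ndarray
    wear: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if len(self.times) != len(self.steps):
            raise ValueError("times and steps length mismatch")
        if len(self.times) and self.times.tz is not None:
            raise ValueError("StepTrace times must be timezone-naive")
        if len(self.times) > 1 and (
            not self.times.is_monotonic_increasing or self.times.has_duplicates
        ):
            raise ValueError("StepTrace times must be strictly increasing")
        if np.any(self.steps < 0):
            raise ValueError("step counts must be >= 0")
        if self.wear is not None:
            self.wear = np.asarray(self.wear, dtype=bool)
            if len(self.wear) != len(self.times):
                raise ValueError("wear mask length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    def steps_between(self, start: pd.Timestamp, end: pd.Timestamp) -> int:
        """Total steps in the half-open window ``[start, end)``."""
        mask = (self.times >= start) & (self.times < end)
        return int(self.steps[mask].sum())

    def wear_minutes_between(self, start: pd.Timestamp, end: pd.Timestamp) -> int:
        mask = (self.times >= start) & (self.times < end)
        if self.wear is None:
            return int(mask.sum())
        return int(self.wear[mask].sum())


@dataclass
class FoodItem:
    name: str
    calories: float
    carbs_g: float = 0.0
    protein_g: float = 0.0
    fat_g: float = 0.0


@dataclass
class FoodLog:
    """One self-reported log entry: a timestamped meal-occasion with items."""

    participant_id: str
    log_time: pd.Timestamp
    occasion: str
    items: list[FoodItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.log_time = _require_naive(pd.Timestamp(self.log_time), "FoodLog")
        if self.occasion not in OCCASIONS:
            raise ValueError(f"unknown occasion {self.occasion!r}")
        for it in self.items:
            if it.calories < 0:
                raise ValueError("item calories must be >= 0")

    @property
    def total_calories(self) -> float:
        return float(sum(it.calories for it in self.items))

    @property
    def key(self) -> str:
        """Stable key referencing this log from annotations."""
        return f"{self.participant_id}|{self.log_time.strftime(TIME_FORMAT)}|{self.occasion}"


@dataclass
class AnnotatedTiming:
    """One annotator's judgement for a meal timing.

    ``source='corrected'`` re-times an existing log (``log_key`` required),
    ``'added'`` marks an unlogged meal (no ``log_key``), ``'unknown'`` tags a
    log whose timing could not be identified (no ``time``).
    """

    participant_id: str
    annotator_id: str
    source: str
    log_key: Optional[str] = None
    time: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.time is not None:
            self.time = _require_naive(pd.Timestamp(self.time), "AnnotatedTiming")
        if (self.source == "unknown") != (self.time is None):
            raise ValueError("source 'unknown' iff time absent")
        if self.source == "corrected" and not self.log_key:
            raise ValueError("corrected timing must reference a log")
        if self.source == "added" and self.log_key:
            raise ValueError("added timing must not reference a log")


@dataclass
class Participant:
    participant_id: str
    hba1c: float
    status: str

    def __post_init__(self) -> None:
        if not (3.0 < self.hba1c < 20.0):
            raise ValueError(f"hba1c {self.hba1c} out of plausible range (3, 20)")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class Bundle:
    """All collections of one study dataset, keyed consistently by participant."""

    participants: list[Participant] = field(default_factory=list)
    glucose: dict[str, GlucoseTrace] = field(default_factory=dict)
    steps: dict[str, StepTrace] = field(default_factory=dict)
    food_logs: list[FoodLog] = field(default_factory=list)
    annotations: list[AnnotatedTiming] = field(default_factory=list)
    rejects: list[RowIssue] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        # unpacks as (participants, glucose, steps, food_logs, annotations)
        return iter(
            (self.participants, self.glucose, self.steps, self.food_logs, self.annotations)
        )

    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def food_log_by_key(self) -> dict[str, FoodLog]:
        return {log.key: log for log in self.food_logs}


# ---------------------------------------------------------------------------
# reading


def _parse_time(raw: str) -> pd.Timestamp:
    ts = pd.Timestamp(str(raw))
    if ts.tzinfo is not None:
        raise ValueError("timezone-aware timestamp")
    return ts


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_bundle(directory: str | Path, nominal_interval: int = 15) -> Bundle:
    """Read and validate a bundle directory.

    Returns a :class:`Bundle`; rows failing invariant checks are collected in
    ``bundle.rejects`` (and logged) rather than raising.  Missing files are
    fatal.
    """
    directory = Path(directory)
    for name in REQUIRED_FILES:
        if not (directory / name).exists():
            raise BundleError(f"missing {name}")

    bundle = Bundle()
    rejects = bundle.rejects

    def reject(fname: str, idx: int, msg: str) -> None:
        issue = RowIssue(fname, idx + 2, msg)  # +2: header + 1-based
        rejects.append(issue)
        logger.warning("rejected row %s", issue)

    # participants
    df = _read_csv(directory / "participants.csv")
    for i, row in df.iterrows():
        try:
            bundle.participants.append(
                Participant(row["participant_id"], float(row["hba1c"]), row["status"])
            )
        except (ValueError, KeyError) as exc:
            reject("participants.csv", i, str(exc))

    # glucose
    df = _read_csv(directory / "glucose.csv")
    per_pid: dict[str, list[tuple[pd.Timestamp, float]]] = {}
    seen: dict[str, set[pd.Timestamp]] = {}
    for i, row in df.iterrows():
        try:
            t = _parse_time(row["time"])
            v = float(row["glucose_mgdl"])
        except (ValueError, KeyError) as exc:
            reject("glucose.csv", i, f"unparsable row: {exc}")
            continue
        if v <= 0:
            reject("glucose.csv", i, f"glucose value must be > 0, got {v}")
            continue
        pid = row["participant_id"]
        if t in seen.setdefault(pid, set()):
            reject("glucose.csv", i, f"duplicate timestamp {t} for {pid}")
            continue
        seen[pid].add(t)
        per_pid.setdefault(pid, []).append((t, v))
    for pid, rows in per_pid.items():
        rows.sort(key=lambda tv: tv[0])
        bundle.glucose[pid] = GlucoseTrace(
            pid,
            pd.DatetimeIndex([t for t, _ in rows]),
            np.array([v for _, v in rows]),
            nominal_interval=nominal_interval,
        )

    # steps
    df = _read_csv(directory / "steps.csv")
    has_wear = "wear" in df.columns
    sper: dict[str, list[tuple[pd.Timestamp, int, bool]]] = {}
    sseen: dict[str, set[pd.Timestamp]] = {}
    for i, row in df.iterrows():
        try:
            t = _parse_time(row["time"])
            s = int(float(row["steps"]))
            w = _parse_bool(row["wear"]) if has_wear else True
        except (ValueError, KeyError) as exc:
            reject("steps.csv", i, f"unparsable row: {exc}")
            continue
        if s < 0:
            reject("steps.csv", i, f"negative step count {s}")
            continue
        pid = row["participant_id"]
        if t in sseen.setdefault(pid, set()):
            reject("steps.csv", i, f"duplicate timestamp {t} for {pid}")
            continue
        sseen[pid].add(t)
        sper.setdefault(pid, []).append((t, s, w))
    for pid, rows in sper.items():
        rows.sort(key=lambda r: r[0])
        bundle.steps[pid] = StepTrace(
            pid,
            pd.DatetimeIndex([t for t, _, _ in rows]),
            np.array([s for _, s, _ in rows]),
            wear=np.array([w for _, _, w in rows]) if has_wear else None,
        )

    # food logs: one row per item, grouped by (participant, time, occasion)
    df = _read_csv(directory / "food_logs.csv")
    groups: dict[tuple, FoodLog] = {}
    for i, row in df.iterrows():
        try:
            t = _parse_time(row["log_time"])
            occ = row["occasion"]
            if occ not in OCCASIONS:
                raise ValueError(f"unknown occasion {occ!r}")
            item = FoodItem(
                row["item_name"],
                float(row["calories"]),
                float(row.get("carbs_g", 0) or 0),
                float(row.get("protein_g", 0) or 0),
                float(row.get("fat_g", 0) or 0),
            )
            if item.calories < 0:
                raise ValueError(f"negative calories {item.calories}")
        except (ValueError, KeyError) as exc:
            reject("food_logs.csv", i, str(exc))
            continue
        keyt = (row["participant_id"], t, occ)
        if keyt not in groups:
            groups[keyt] = FoodLog(row["participant_id"], t, occ, [])
        groups[keyt].items.append(item)
    bundle.food_logs = sorted(
        groups.values(), key=lambda g: (g.participant_id, g.log_time, g.occasion)
    )

    # annotations
    df = _read_csv(directory / "annotations.csv")
    for i, row in df.iterrows():
        try:
            time_raw = row.get("time", "")
            time = _parse_time(time_raw) if time_raw else None
            log_key = row.get("log_key", "") or None
            bundle.annotations.append(
                AnnotatedTiming(
                    row["participant_id"], row["annotator_id"], row["source"], log_key, time
                )
            )
        except (ValueError, KeyError) as exc:
            reject("annotations.csv", i, str(exc))

    return bundle


def _parse_bool(raw: str) -> bool:
    s = str(raw).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"unparsable boolean {raw!r}")


# ---------------------------------------------------------------------------
# writing


def write_bundle(bundle: Bundle, directory: str | Path) -> dict[str, int]:
    """Write a bundle to ``directory``; returns {file name: data row count}.

    ``read_bundle(write_bundle(b))`` round-trips content exactly (timestamps
    to the minute).  Timezone-aware timestamps are rejected before any file
    is written.
    """
    directory = Path(directory)
    _validate_naive(bundle)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise BundleError(f"unwritable path {directory}: {exc}") from exc

    manifest: dict[str, int] = {}

    rows = [
        {"participant_id": p.participant_id, "hba1c": p.hba1c, "status": p.status}
        for p in bundle.participants
    ]
    manifest["participants.csv"] = _write(
        directory / "participants.csv", rows, ["participant_id", "hba1c", "status"]
    )

    rows = [
        {
            "participant_id": pid,
            "time": t.strftime(TIME_FORMAT),
            "glucose_mgdl": f"{v:.6g}",
        }
        for pid, trace in sorted(bundle.glucose.items())
        for t, v in zip(trace.times, trace.values)
    ]
    manifest["glucose.csv"] = _write(
        directory / "glucose.csv", rows, ["participant_id", "time", "glucose_mgdl"]
    )

    any_wear = any(tr.wear is not None for tr in bundle.steps.values())
    srows = []
    for pid, trace in sorted(bundle.steps.items()):
        wear = trace.wear if trace.wear is not None else np.ones(len(trace), bool)
        for t, s, w in zip(trace.times, trace.steps, wear):
            row = {"participant_id": pid, "time": t.strftime(TIME_FORMAT), "steps": int(s)}
            if any_wear:
                row["wear"] = int(w)
            srows.append(row)
    cols = ["participant_id", "time", "steps"] + (["wear"] if any_wear else [])
    manifest["steps.csv"] = _write(directory / "steps.csv", srows, cols)

    frows = [
        {
            "participant_id": log.participant_id,
            "log_time": log.log_time.strftime(TIME_FORMAT),
            "occasion": log.occasion,
            "item_name": item.name,
            "calories": f"{item.calories:.6g}",
            "carbs_g": f"{item.carbs_g:.6g}",
            "protein_g": f"{item.protein_g:.6g}",
            "fat_g": f"{item.fat_g:.6g}",
        }
        for log in bundle.food_logs
        for item in log.items
    ]
    manifest["food_logs.csv"] = _write(
        directory / "food_logs.csv",
        frows,
        [
            "participant_id",
            "log_time",
            "occasion",
            "item_name",
            "calories",
            "carbs_g",
            "protein_g",
            "fat_g",
        ],
    )

    arows = [
        {
            "participant_id": a.participant_id,
            "annotator_id": a.annotator_id,
            "source": a.source,
            "log_key": a.log_key or "",
            "time": a.time.strftime(TIME_FORMAT) if a.time is not None else "",
        }
        for a in bundle.annotations
    ]
    manifest["annotations.csv"] = _write(
        directory / "annotations.csv",
        arows,
        ["participant_id", "annotator_id", "source", "log_key", "time"],
    )
    return manifest


def _validate_naive(bundle: Bundle) -> None:
    for trace in list(bundle.glucose.values()) + list(bundle.steps.values()):
        if len(trace.times) and trace.times.tz is not None:
            raise ValueError("timezone-aware timestamps are not writable")
    for log in bundle.food_logs:
        _require_naive(log.log_time, "FoodLog")
    for a in bundle.annotations:
        if a.time is not None:
            _require_naive(a.time, "AnnotatedTiming")


def _write(path: Path, rows: Sequence[dict], columns: list[str]) -> int:
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)
    return len(df)
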