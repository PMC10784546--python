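"""End-to-end orchestration: simulate/load -> segment -> biomarkers -> daily
-> causal -> figures, tables, and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (
    HbA1cMapper,
    compute_event_biomarkers,
    fit_hba1c_mapper,
    mean_mgr_by_participant,
    mgr_3h,
)
from .causal import balance_to_frame, effects_to_frame, run_study_analyses
from .daily import (
    adherence_summary,
    build_day_records,
    day_records_to_frame,
    included_day_table,
)
from .io_schemas import Bundle, read_bundle, write_bundle
from .meal_events import MealEvent, events_to_frame, segment_meal_events
from .synthetic_data import (
    SimulationConfig,
    config_to_dict,
    ground_truth_to_csv,
    simulate_annotators,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    bundle_path: Optional[str] = None  # when None, simulate
    sim_config: SimulationConfig = field(default_factory=SimulationConfig)
    tir_lower: float = 54.0
    mapper_degree: int = 1
    stabilized_weights: bool = True
    truncate_weights: bool = True
    out_dir: str = "results"
    rng_seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.tir_lower not in (54.0, 70.0, 54, 70):
            raise ValueError("tir_lower must be 54 or 70")
        if self.mapper_degree not in (1, 2):
            raise ValueError("mapper_degree must be 1 or 2")

    def to_dict(self) -> dict:
        return {
            "bundle_path": self.bundle_path,
            "sim_config": config_to_dict(self.sim_config),
            "tir_lower": float(self.tir_lower),
            "mapper_degree": self.mapper_degree,
            "stabilized_weights": self.stabilized_weights,
            "truncate_weights": self.truncate_weights,
            "rng_seed": self.rng_seed,
        }


def event_mgr_table(events: list[MealEvent]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": e.participant_id,
            "start_time": e.start_time,
            "mgr_3h": mgr_3h(e.segment_minutes, e.segment_values, e.baseline_glucose),
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=["participant_id", "start_time", "mgr_3h"])


def fit_mapper_for_bundle(
    bundle: Bundle, events: list[MealEvent], degree: int = 1
) -> HbA1cMapper:
    mean_mgr = mean_mgr_by_participant(event_mgr_table(events))
    hba1c = {p.participant_id: p.hba1c for p in bundle.participants}
    return fit_hba1c_mapper(mean_mgr, hba1c, degree=degree)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the result directory.

    Writes: the input bundle (when simulated) plus ``ground_truth.csv``,
    ``meal_events.csv``, ``meal_biomarkers.csv``, ``mapper.json``,
    ``day_records.csv``, ``adherence.csv``, ``effects.csv``, ``balance.csv``,
    figures, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire data
    truth = None
    try:
        if config.bundle_path is not None:
            bundle = read_bundle(config.bundle_path)
        else:
            sim = config.sim_config
            sim.rng_seed = config.rng_seed
            bundle, truth = simulate_cohort(sim)
            simulate_annotators(bundle, truth)
            write_bundle(bundle, out / "bundle")
            ground_truth_to_csv(truth, out / "ground_truth.csv")
    except Exception as exc:
        raise StageError("acquire", exc) from exc

    # --- segmentation
    try:
        events = segment_meal_events(bundle)
        events_to_frame(events).to_csv(out / "meal_events.csv", index=False)
    except Exception as exc:
        raise StageError("segment", exc) from exc

    # --- biomarkers
    try:
        mapper = fit_mapper_for_bundle(bundle, events, degree=config.mapper_degree)
        status = {p.participant_id: p.status for p in bundle.participants}
        biomarker_table = compute_event_biomarkers(
            events, bundle.steps, bundle.food_log_by_key(), mapper, status
        )
        biomarker_table.to_csv(out / "meal_biomarkers.csv", index=False)
        (out / "mapper.json").write_text(mapper.to_json())
    except Exception as exc:
        raise StageError("biomarkers", exc) from exc

    # --- daily records and adherence
    try:
        records = build_day_records(
            bundle, events, biomarker_table, tir_lower=config.tir_lower
        )
        day_records_to_frame(records).to_csv(out / "day_records.csv", index=False)
        per_participant, cohort = adherence_summary(bundle)
        per_participant.to_csv(out / "adherence.csv", index=False)
        (out / "adherence_cohort.json").write_text(json.dumps(cohort, indent=2))
        day_table = included_day_table(records)
    except Exception as exc:
        raise StageError("daily", exc) from exc

    # --- causal analysis
    try:
        results = run_study_analyses(
            day_table,
            biomarker_table,
            stabilized=config.stabilized_weights,
            truncate=config.truncate_weights,
        )
        effects_to_frame(results).to_csv(out / "effects.csv", index=False)
        balance_to_frame(results).to_csv(out / "balance.csv", index=False)
    except Exception as exc:
        raise StageError("causal", exc) from exc

    # --- figures
    if config.make_figures:
        try:
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            _mapper_figure(mapper, figdir / "mapper_fit.png")
            _tir_by_count_figure(day_table, bundle, figdir / "tir_by_elevated_count.png")
        except Exception as exc:
            raise StageError("figures", exc) from exc

    # --- manifest
    cfg = config.to_dict()
    manifest = {
        "glycophen_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.rng_seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_meal_events": len(events),
        "n_included_days": int(len(day_table)),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _mapper_figure(mapper: HbA1cMapper, path: Path) -> None:
    diag = mapper.diagnostics
    x = np.asarray(diag.get("mean_mgr", []), dtype=float)
    y = np.asarray(diag.get("hba1c_true", []), dtype=float)
    fitted = np.asarray(diag.get("hba1c_fitted", []), dtype=float)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    if len(x):
        axes[0].scatter(x, y, s=18)
        grid = np.linspace(x.min(), x.max(), 100)
        axes[0].plot(grid, mapper.predict(grid), "k-")
    axes[0].set_xlabel("mean 3-h meal glucose response (min·mg/dL)")
    axes[0].set_ylabel("HbA1c (%)")
    axes[0].set_title("Robust fit (synthetic data)")
    if len(y):
        axes[1].scatter(y, fitted, s=18)
        lims = [min(y.min(), fitted.min()), max(y.max(), fitted.max())]
        axes[1].plot(lims, lims, "k--")
    axes[1].set_xlabel("true HbA1c (%)")
    axes[1].set_ylabel("fitted HbA1c (%)")
    r = diag.get("overall", {}).get("pearson_r", float("nan"))
    axes[1].set_title(f"true vs fitted (r = {r:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _tir_by_count_figure(day_table: pd.DataFrame, bundle: Bundle, path: Path) -> None:
    status = {p.participant_id: p.status for p in bundle.participants}
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, st in zip(axes, ("at_risk", "prediabetes", "t2d")):
        if len(day_table):
            sub = day_table[day_table["participant_id"].map(status) == st]
        else:
            sub = day_table
        data = [
            sub[sub["elevated_count_category"] == c]["tir"].dropna() for c in range(4)
        ]
        ax.boxplot(data, tick_labels=["0", "1", "2", "≥3"])
        ax.set_title(st)
        ax.set_xlabel("elevated meal event count")
    axes[0].set_ylabel("daily TIR (%)")
    fig.suptitle("Daily TIR by elevated meal count (synthetic data)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
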