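import numpy as np
import pandas as pd
import pytest

from glycophen.io_schemas import (
    AnnotatedTiming,
    Bundle,
    FoodItem,
    FoodLog,
    GlucoseTrace,
    Participant,
    StepTrace,
)
from glycophen.synthetic_data import (
    AnnotatorModel,
    LoggingErrorModel,
    SimulationConfig,
    simulate_annotators,
    simulate_cohort,
)

T0 = pd.Timestamp("2022-03-01")


def ts(spec: str) -> pd.Timestamp:
    """'d1 08:30' -> timestamp on study day 1."""
    day, hm = spec.split()
    return T0 + pd.Timedelta(days=int(day[1:])) + pd.Timedelta(
        hours=int(hm.split(":")[0]), minutes=int(hm.split(":")[1])
    )


def flat_trace(pid="P1", start="d0 00:00", hours=24, value=100.0, interval=15):
    times = pd.date_range(ts(start), periods=int(hours * 60 / interval), freq=f"{interval}min")
    return GlucoseTrace(pid, times, np.full(len(times), float(value)), interval)


def bump_trace(pid="P1", start="d0 00:00", hours=24, baseline=100.0, bumps=(), interval=15):
    """Flat trace plus triangular bumps: (center_spec, half_width_min, height)."""
    trace = flat_trace(pid, start, hours, baseline, interval)
    values = trace.values.copy()
    for center, half_width, height in bumps:
        c = ts(center)
        dt = np.abs((trace.times - c).total_seconds().to_numpy()) / 60.0
        values += height * np.clip(1 - dt / half_width, 0, None)
    trace.values = values
    return trace


@pytest.fixture
def tiny_bundle() -> Bundle:
    """Hand-built 2-participant bundle with one meal each."""
    bundle = Bundle()
    bundle.participants = [
        Participant("P1", 5.9, "prediabetes"),
        Participant("P2", 6.8, "t2d"),
    ]
    for pid in ("P1", "P2"):
        bundle.glucose[pid] = bump_trace(pid, bumps=[("d0 09:00", 60, 40.0)])
        times = pd.date_range(ts("d0 00:00"), periods=1440, freq="min")
        steps = np.zeros(1440, dtype=int)
        steps[8 * 60 : 8 * 60 + 60] = 50
        wear = np.zeros(1440, dtype=bool)
        wear[6 * 60 : 22 * 60] = True
        bundle.steps[pid] = StepTrace(pid, times, steps, wear=wear)
        bundle.food_logs.append(
            FoodLog(pid, ts("d0 08:10"), "breakfast", [FoodItem("oatmeal", 300.0, 50, 10, 5)])
        )
    for pid in ("P1", "P2"):
        key = bundle.food_logs[0 if pid == "P1" else 1].key
        for a in ("A1", "A2", "A3", "A4"):
            bundle.annotations.append(
                AnnotatedTiming(pid, a, "corrected", key, ts("d0 08:00"))
            )
    return bundle


NOISE_FREE = dict(
    base_mgr_mean=3500.0,
    base_mgr_sd=400.0,
    walk_steps_mean=400.0,
    walk_steps_sd=200.0,
    mgr_noise_sd=0.0,
    hba1c_noise_sd=0.0,
    cgm_noise_sd=0.0,
    logging_error_model=LoggingErrorModel(0.0, 0.0, 0.0),
    annotator_model=AnnotatorModel(0.0, 0.0, 1.0),
)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Deterministic, fully observed cohort: every meal logged and annotated
    at its exact start; amplitudes all clear the qualification threshold."""
    cfg = SimulationConfig(n_participants=8, n_days=7, rng_seed=11, **NOISE_FREE)
    bundle, truth = simulate_cohort(cfg)
    simulate_annotators(bundle, truth)
    assert (truth.meals["peak_amplitude"] >= 18.6).all()
    return bundle, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Small cohort with the default noise models switched on."""
    cfg = SimulationConfig(n_participants=6, n_days=7, rng_seed=3)
    bundle, truth = simulate_cohort(cfg)
    simulate_annotators(bundle, truth)
    return bundle, truth
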