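# glycophen

Multimodal digital phenotyping of diet, physical activity, and glycemia.
From synchronized CGM glucose, minute-level step counts, self-reported food
logs, and multi-annotator meal-timing corrections, the pipeline:

1. **segments meal events** — staged food logs of one occasion are merged
   within 60 min; timings from multiple annotators are aggregated per
   participant-day with 1-D DBSCAN (eps = 1.5 h, min_samples = 2); within
   each group the timing with the largest 3-h incremental glucose AUC is the
   event start; events qualify when the 3-h segment rises ≥ 18.6 mg/dL above
   the start baseline and start between 04:00 and 23:59;
2. **computes meal-event biomarkers** — the 3-h meal glucose response
   (baseline-subtracted, negative-clipped trapezoidal iAUC, min·mg/dL),
   post-meal step count (1-h window), calorie content, and an
   elevated/normal label obtained by mapping each event's response through a
   cohort-level robust (Huber) regression onto HbA1c (thresholds 5.7% for
   at-risk/prediabetes, 6.5% for T2D, inclusive);
3. **builds participant-day records** — analysis window from meal and wear
   times, elevated meal event count (0/1/2/≥3), daily steps, baseline
   glucose, time-in-range 54–140 mg/dL (70 mg/dL lower bound as a
   sensitivity option), mean glucose, with day-exclusion rules (no meals,
   < 10 h wear, incomplete CGM day, sensor-limit readings ≤ 40 / ≥ 500
   mg/dL) and per-modality adherence summaries;
4. **estimates causal effects** — generalized propensity scores (linear
   mixed model + normal density for continuous treatments; multinomial
   model for the elevated-count categories), stabilized and truncated
   inverse probability weights, covariate balance diagnostics (|r| < 0.1,
   SMD < 0.2), and doubly-robust weighted cluster regressions (participant
   multilevel structure) of elevated meal count, daily steps, post-meal
   steps, and calories on glycemic outcomes.

A first-class synthetic-data module generates full multimodal cohorts with
known ground truth — planted meal times and excursion shapes, planted
calorie/step effects, a linear participant-level response→HbA1c map,
logging errors (missed, delayed, end-of-day batch logs), emulated
annotators, and a separate confounded participant-day generator for
validating the causal estimators — so the entire pipeline runs and is
tested without any external data.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the heavy property-based validation
(segmentation recovery, mapper parameter recovery, Monte-Carlo causal
estimator validation incl. a 500-seed type-I error study); expect ~8 min
for the full suite on one CPU.

## CLI

```bash
# simulate a synthetic bundle (CSV files + ground_truth.csv)
glycophen simulate --seed 1 --out data/bundle

# stage by stage
glycophen segment --bundle data/bundle --out results
glycophen biomarkers --bundle data/bundle --out results
glycophen daily --bundle data/bundle --biomarkers results/meal_biomarkers.csv --out results
glycophen causal --day-records results/day_records.csv \
    --biomarkers results/meal_biomarkers.csv --out results

# or everything at once (simulate -> segment -> biomarkers -> daily -> causal)
glycophen run --seed 1 --out results [--tir-lower 70] [--mapper-degree 2]
```

`glycophen run` writes `meal_events.csv`, `meal_biomarkers.csv`,
`mapper.json`, `day_records.csv`, `adherence.csv`, `effects.csv`,
`balance.csv`, figures, and a reproducibility `manifest.json`; identical
seeds give byte-identical outputs. A YAML file passed via `--config` can
override any simulation setting (see `SimulationConfig` in
`glycophen.synthetic_data`).

## Data formats

A *bundle* is a directory of five CSVs (UTF-8, header row, timezone-naive
ISO-8601 minute timestamps): `glucose.csv`, `steps.csv`, `food_logs.csv`
(one row per food item), `annotations.csv`, `participants.csv`. See
`glycophen/io_schemas.py` for column contracts; invalid rows are rejected
with row-level diagnostics, never silently dropped.
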