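"""CSV interchange for study datasets and measure tables.

All data move through four tidy CSVs (reflex trials, conditioning counts,
place-test compartment times, animal roster) plus a wide ``measures.csv``
whose header uses the exact outcome-measure names, and a JSON sidecar with
the transform flags.  Reading validates every type invariant (latency
window, non-negative counts, compartment-time composition, paired VEH/OXY
sessions) before any computation starts and names the offending file, row
and column on failure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .measures import ALL_MEASURES, MeasureTable
from .synthetic import (
    LATENCY_MAX_S,
    LATENCY_MIN_S,
    GeneratorConfig,
    StudyDataset,
)

__all__ = [
    "DATASET_FILES", "write_dataset", "read_dataset",
    "write_measures", "read_measures", "write_config_echo", "dataset_hashes",
]

DATASET_FILES = {
    "reflex_trials": ("animal", "day", "session", "paw", "trial_index", "latency_s"),
    "conditioning": ("animal", "day", "drug", "counts"),
    "place_tests": ("animal", "day", "compartment", "time_s"),
    "animals": ("animal", "sex", "surgery_arm", "surgeried_paw"),
}

_COMPOSITION_TOL_S = 1e-6


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tidy CSVs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in DATASET_FILES:
        path = out_dir / f"{name}.csv"
        getattr(dataset, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def _require_columns(df: pd.DataFrame, name: str, columns: tuple[str, ...]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}.csv: missing columns {missing}")


def validate_dataset(dataset: StudyDataset, test_length_s: float | None = None) -> None:
    """Enforce every schema invariant; raises ValidationError with location."""
    rx = dataset.reflex_trials
    bad = rx[(rx["latency_s"] < LATENCY_MIN_S) | (rx["latency_s"] > LATENCY_MAX_S)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"reflex_trials.csv: latency_s {row['latency_s']} outside "
            f"[{LATENCY_MIN_S}, {LATENCY_MAX_S}] (animal {row['animal']}, "
            f"day {row['day']}, paw {row['paw']})")
    counts = rx.groupby(["animal", "day", "paw"]).size()
    if (counts < 2).any():
        animal, day, paw = counts[counts < 2].index[0]
        raise ValidationError(
            f"reflex_trials.csv: fewer than 2 trials (animal {animal}, "
            f"day {day}, paw {paw})")

    cond = dataset.conditioning
    if (cond["counts"] < 0).any():
        row = cond[cond["counts"] < 0].iloc[0]
        raise ValidationError(
            f"conditioning.csv: negative counts (animal {row['animal']}, "
            f"day {row['day']}, drug {row['drug']})")
    per_day = cond.pivot_table(index=["animal", "day"], columns="drug",
                               values="counts", aggfunc="count")
    for drug in ("VEH", "OXY"):
        if drug not in per_day.columns or not (per_day[drug] == 1).all():
            raise ValidationError(
                f"conditioning.csv: every animal-day needs exactly one {drug} record")

    pt = dataset.place_tests
    if (pt["time_s"] < 0).any():
        row = pt[pt["time_s"] < 0].iloc[0]
        raise ValidationError(
            f"place_tests.csv: negative time_s (animal {row['animal']}, "
            f"day {row['day']}, compartment {row['compartment']})")
    totals = pt.groupby(["animal", "day"])["time_s"].sum()
    ref = test_length_s if test_length_s is not None else float(totals.iloc[0])
    off = totals[(totals - ref).abs() > _COMPOSITION_TOL_S]
    if len(off):
        animal, day = off.index[0]
        raise ValidationError(
            f"place_tests.csv: compartment times sum to {off.iloc[0]:.3f}, "
            f"expected {ref:.3f} (animal {animal}, day {day})")

    arms = set(dataset.animals["surgery_arm"].unique())
    if not arms <= {"sham", "cci"}:
        raise ValidationError(f"animals.csv: unknown surgery_arm values {arms - {'sham', 'cci'}}")


def read_dataset(in_dir: str | Path, validate: bool = True,
                 test_length_s: float | None = None) -> StudyDataset:
    """Load the four tidy CSVs and (by default) validate them."""
    in_dir = Path(in_dir)
    frames = {}
    for name, columns in DATASET_FILES.items():
        path = in_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path)
        _require_columns(df, name, columns)
        frames[name] = df
    dataset = StudyDataset(**frames)
    if validate:
        validate_dataset(dataset, test_length_s=test_length_s)
    return dataset


def write_measures(table: MeasureTable, path: str | Path) -> Path:
    """Write the wide measures CSV plus a transform-flag JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=True)
    sidecar = path.with_suffix(".flags.json")
    sidecar.write_text(json.dumps(table.transform_flags, ensure_ascii=False, indent=1))
    return path


def read_measures(path: str | Path) -> MeasureTable:
    path = Path(path)
    data = pd.read_csv(path, index_col=0)
    unknown = [c for c in data.columns if c not in ALL_MEASURES]
    if unknown:
        raise ValidationError(f"{path.name}: unknown measure columns {unknown}; "
                              f"valid: {list(ALL_MEASURES)}")
    sidecar = path.with_suffix(".flags.json")
    flags = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return MeasureTable(data=data, transform_flags=flags)


def write_config_echo(config: GeneratorConfig, path: str | Path) -> Path:
    """Echo the generator configuration as YAML for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        payload[f.name] = v
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def dataset_hashes(in_dir: str | Path) -> dict[str, str]:
    """SHA-256 of each dataset CSV, for reproducibility logging."""
    import hashlib

    out = {}
    for name in DATASET_FILES:
        path = Path(in_dir) / f"{name}.csv"
        if path.exists():
            out[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return out
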