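"""Plain-text I/O, run configuration and the end-to-end pipeline runner.

All tables are plain CSV (UTF-8, '.' decimal separator) and all summaries
JSON, so every artefact is diffable; each output carries provenance
metadata (config hash, seed, package version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import experiments
from .analysis import classify_unit, population_summary
from .model import ModelParameters
from .population import (
    PopulationSpec,
    SpikeTrain,
    UnitSpec,
    default_unit,
    generate_trials,
    sample_population,
)
from .protocols import ProtocolSchedule, build_protocol, schedule_from_table, schedule_to_table

__all__ = [
    "TableFormatError",
    "read_tables",
    "write_events",
    "read_events",
    "write_spikes",
    "read_spikes",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("scadapt")

_SPIKE_COLUMNS = ["unit_id", "spike_time_s"]


class TableFormatError(ValueError):
    """Raised for malformed input tables, with row-level diagnostics."""


def write_events(schedule: ProtocolSchedule, path: str | Path) -> None:
    schedule_to_table(schedule).to_csv(path, index=False)


def read_events(path: str | Path, kind: str = "flash_train") -> ProtocolSchedule:
    df = _read_csv(path)
    _validate_events(df)
    return schedule_from_table(df, kind)


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=_SPIKE_COLUMNS).to_csv(path, index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _validate_spikes(df)
    return df


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        # round_trip parsing so written schedules reload bit-identically
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message pass-through
        raise TableFormatError(f"{path}: {exc}") from exc


def _validate_spikes(df: pd.DataFrame) -> None:
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"spike table missing columns: {missing}")
    if df.empty:
        return  # an empty spike file with a valid header is not an error
    if not np.issubdtype(df["spike_time_s"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["spike_time_s"], errors="coerce").isna()]
        raise TableFormatError(
            f"non-numeric spike_time_s at rows {list(bad[:5])}")
    for uid, grp in df.groupby("unit_id"):
        t = grp["spike_time_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise TableFormatError(
                f"unsorted spike times for unit {uid} at row {row}")


def _validate_events(df: pd.DataFrame) -> None:
    required = ["trial_id", "role", "t_on_s", "t_off_s", "x_deg", "y_deg",
                "diameter_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"event table missing columns: {missing}")
    for col in ("t_on_s", "t_off_s", "x_deg", "y_deg", "diameter_deg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if bad.size:
            raise TableFormatError(f"non-numeric {col} at row {bad[0]}")
    bad = df.index[df["t_off_s"] <= df["t_on_s"]]
    if bad.size:
        raise TableFormatError(f"t_off_s <= t_on_s at row {bad[0]}")


def read_tables(spikes_path: str | Path, events_path: str | Path,
                kind: str = "flash_train") -> tuple[pd.DataFrame, ProtocolSchedule]:
    """Read and validate a spike table and an event table."""
    spikes = read_spikes(spikes_path)
    events = read_events(events_path, kind)
    return spikes, events


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    seed: int = 0
    n_units: int = 31
    noiseless: bool = True
    n_trials: int = 8  # Poisson trials per condition when noiseless=False
    alpha: float = 0.05
    include_model: bool = False  # also run the mechanistic-model experiments
    population: dict = field(default_factory=dict)  # PopulationSpec overrides
    model: dict = field(default_factory=dict)  # ModelParameters overrides

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Generate a synthetic population, analyze it, and summarize.

    Runs the calibration battery on the population-mean unit (flash-train
    reductions, onset time constants, 11 s recovery, displacement d50) plus
    population-level statistics over the sampled units; optionally also the
    mechanistic-model experiments.  Writes CSV/JSON outputs when ``out_dir``
    is given and returns the summary dict either way.
    """
    pop_spec = PopulationSpec(n_units=config.n_units, seed=config.seed,
                              **config.population)
    units = sample_population(pop_spec)
    unit = default_unit()

    log.info("measuring calibration battery on the population-mean unit")
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "n_units": len(units),
        "second_on_reduction_pct": experiments.unit_flash_train_reduction(unit, "ON"),
        "second_off_reduction_pct": experiments.unit_flash_train_reduction(unit, "OFF"),
        "tau_on_s": experiments.unit_onset_tau(unit, "ON").tau,
        "tau_off_s": experiments.unit_onset_tau(unit, "OFF").tau,
        "recovery_11s_off_pct": experiments.unit_recovery_fraction(unit, "OFF"),
        "recovery_11s_on_pct": experiments.unit_recovery_fraction(unit, "ON"),
        "d50_on_deg": experiments.unit_displacement_d50(unit, "ON").d50,
    }

    reductions = [u.second_on_reduction() for u in units]
    small = [u.rf_diameter < pop_spec.small_rf_threshold for u in units]
    summary["population"] = {
        "second_on_reduction": population_summary(reductions),
        "fraction_small_rf": float(np.mean(small)),
    }

    unit_rows = [dataclasses.asdict(u) for u in units]
    classifications = None
    if not config.noiseless:
        log.info("classifying %d units from %d Poisson trials each",
                 len(units), config.n_trials)
        classifications = _classify_population(units, config)
        summary["n_adapting_on"] = int(
            sum(c == "adapting" for c in classifications))
    else:
        summary["n_adapting_on"] = int(
            sum(u.second_on_reduction() > 1e-6 for u in units))

    if config.include_model:
        params = ModelParameters(**config.model)
        log.info("running mechanistic-model battery")
        summary["model"] = {
            "second_on_reduction_pct": experiments.model_flash_train_reduction(params),
            "recovery_11s_on_pct": experiments.model_recovery_fraction(params),
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(unit_rows).to_csv(out / "units.csv", index=False)
        if classifications is not None:
            pd.DataFrame({"unit": range(len(units)),
                          "classification": classifications}).to_csv(
                out / "classifications.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("outputs written to %s", out)
    return summary


def _classify_population(units: list[UnitSpec], config: RunConfig) -> list[str]:
    from .analysis import ON_WINDOW

    sched = build_protocol("flash_train", n_flashes=6)
    results = []
    for i, u in enumerate(units):
        trains = generate_trials(u, sched, config.n_trials,
                                 seed=config.seed * 100003 + i)
        counts: dict[float, list[int]] = {}
        for k, ev in enumerate(sched.events):
            lo, hi = ev.t_on + ON_WINDOW[0], ev.t_on + ON_WINDOW[1]
            counts[float(k)] = [
                int(np.count_nonzero((tr.times >= lo) & (tr.times < hi)))
                for tr in trains]
        results.append(classify_unit(counts, alpha=config.alpha))
    return results
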