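"""Plain-text session storage.

A session directory holds the generator config (YAML), the pool ground
truth (JSON), the ramp-trial drive/force/spike data (CSV), the thresholds
table (CSV), per-trial task logs (JSON lines, one object per buffer) and
analysis outputs (CSV/JSON).  All formats carry a ``format_version``.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import DriveTrace, ForceTrace, SpikeTrain
from .engine import SessionRecord
from .synth import MotorUnitParams, MotorUnitPool, SimulationConfig

FORMAT_VERSION = 1

__all__ = [
    "FORMAT_VERSION", "write_spike_trains", "read_spike_trains",
    "write_trace", "read_trace", "write_pool", "read_pool", "write_config",
    "read_config", "write_thresholds", "read_thresholds",
    "write_session_trials", "write_summary",
]


def write_spike_trains(path, trains: Sequence[SpikeTrain]) -> None:
    rows = [(tr.unit_id, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_spike_trains(path) -> List[SpikeTrain]:
    df = pd.read_csv(path)
    return [SpikeTrain(str(uid), np.sort(sub["time_s"].to_numpy(dtype=float)))
            for uid, sub in df.groupby("unit_id", sort=True)]


def write_trace(path, trace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace(path, kind: str = "force"):
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    cls = ForceTrace if kind == "force" else DriveTrace
    return cls(fs=fs, values=df["value"].to_numpy(dtype=float), t0=float(t[0]))


def write_pool(path, pool: MotorUnitPool) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "units": [dataclasses.asdict(u) for u in pool.units],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_pool(path) -> MotorUnitPool:
    payload = json.loads(Path(path).read_text())
    return MotorUnitPool(tuple(MotorUnitParams(**u)
                               for u in payload["units"]))


def write_config(path, config: SimulationConfig) -> None:
    payload = dataclasses.asdict(config)
    payload["format_version"] = FORMAT_VERSION
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config(path) -> SimulationConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload.pop("format_version", None)
    for key in ("threshold_range", "r_min_range", "rate_gain_range",
                "r_sat_increment_range"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    return SimulationConfig(**payload)


def write_thresholds(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_thresholds(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_session_trials(directory, session: SessionRecord) -> None:
    """Per-buffer trial logs as JSON lines plus a per-trial events file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events = {"format_version": FORMAT_VERSION,
              "target_order": list(session.target_order),
              "gains": list(session.gains),
              "ref_rates": list(session.ref_rates),
              "seed": session.seed,
              "trials": []}
    with open(directory / "trials.jsonl", "w") as fh:
        for k, st in enumerate(session.trials):
            trial = st.trial
            for i in range(trial.n_buffers):
                fh.write(json.dumps({
                    "trial_id": k, "buffer": i, "t": round(float(trial.t[i]), 6),
                    "x": round(float(trial.positions[i, 0]), 6),
                    "y": round(float(trial.positions[i, 1]), 6),
                    "region": trial.regions[i]}) + "\n")
            events["trials"].append({
                "trial_id": k, "target": trial.target_id,
                "outcome": trial.outcome,
                "angle_hit_buffer": trial.angle_hit_buffer,
                "target_hit_buffer": trial.target_hit_buffer,
                "onset_time": trial.onset_time,
                "spikes_mu1": [round(float(t), 6) for t in st.trains[0].times],
                "spikes_mu2": [round(float(t), 6) for t in st.trains[1].times],
            })
    (directory / "events.json").write_text(json.dumps(events, indent=1))


def write_summary(path, summary_dict: Dict) -> None:
    payload = {"format_version": FORMAT_VERSION}
    payload.update(summary_dict)
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
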