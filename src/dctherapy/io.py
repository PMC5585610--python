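"""Configuration documents and trajectory serialization.

Configuration is a single YAML document with optional sections ``params``
(flat, keyed by the model's symbol names), ``therapy``, ``schedule`` and
``optimizer``; an empty document yields the published defaults.  Unknown
keys anywhere are schema errors listing the offenders.

Trajectories round-trip as CSV (17 significant digits) with a JSON sidecar
logging the impulse events exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import STATE_NAMES, ModelParams
from .optimize import OptimizerConfig
from .simulate import Schedule, TherapyConfig, Trajectory

__all__ = [
    "Config",
    "default_params_path",
    "load_config",
    "save_config",
    "load_params",
    "save_params",
    "write_trajectory",
    "read_trajectory",
]

_CSV_HEADER = ("time",) + STATE_NAMES


class ConfigError(ValueError):
    """Malformed or unit-violating configuration document."""


@dataclass(frozen=True)
class Config:
    params: ModelParams
    therapy: TherapyConfig
    schedule: Schedule
    optimizer: OptimizerConfig


def _build_section(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {', '.join(unknown)}")
    coerced = {}
    try:
        for k, v in data.items():
            # YAML 1.1 reads "1.0e6" as a string; coerce per the field type
            ftype = str(fields[k].type)
            if "bool" in ftype:
                coerced[k] = bool(v)
            elif "float" in ftype:
                coerced[k] = float(v)
            elif "int" in ftype:
                coerced[k] = int(v)
            else:
                coerced[k] = v
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path) -> Config:
    """Load and validate a full configuration document.

    Missing sections (or an empty document) fall back to defaults:
    the published parameter table, ``tau = 232`` h / ``e_f = 0.05`` therapy,
    an empty 1000 h schedule, and golden-section descent.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = sorted(set(doc) - {"params", "therapy", "schedule", "optimizer"})
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(unknown)}")

    try:
        params = ModelParams.from_dict(doc.get("params") or {})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    therapy = _build_section(TherapyConfig, doc.get("therapy") or {}, "therapy")

    sched_doc = dict(doc.get("schedule") or {})
    unknown = sorted(set(sched_doc) - {"times", "t_f"})
    if unknown:
        raise ConfigError(f"unknown key(s) in section 'schedule': {', '.join(unknown)}")
    schedule = Schedule(sched_doc.get("times") or [], float(sched_doc.get("t_f", 1000.0)))

    optimizer = _build_section(OptimizerConfig, doc.get("optimizer") or {}, "optimizer")
    return Config(params=params, therapy=therapy, schedule=schedule, optimizer=optimizer)


def save_config(cfg: Config, path) -> None:
    doc = {
        "params": cfg.params.to_dict(),
        "therapy": dataclasses.asdict(cfg.therapy),
        "schedule": {"times": list(cfg.schedule.times), "t_f": cfg.schedule.t_f},
        "optimizer": dataclasses.asdict(cfg.optimizer),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_params_path() -> Path:
    """Path of the bundled default parameter document."""
    return Path(resources.files("dctherapy") / "data" / "default_params.yaml")


def load_params(path) -> ModelParams:
    """Load a flat parameter document keyed by symbol names."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError("parameter document must be a flat mapping")
    try:
        return ModelParams.from_dict(doc)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_params(params: ModelParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def write_trajectory(traj: Trajectory, csv_path, events_path=None) -> None:
    """Write a trajectory as CSV plus a JSON impulse-event sidecar.

    Values are printed with 17 significant digits, so the round-trip is
    lossless for doubles.  ``events_path`` defaults to the CSV path with an
    ``.events.json`` suffix.
    """
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        np.column_stack([traj.times, traj.states]), columns=list(_CSV_HEADER)
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    events_path = Path(events_path) if events_path else csv_path.with_suffix(".events.json")
    events_path.write_text(
        json.dumps({"events": [{"time": t, "jump": j} for t, j in traj.events]}, indent=1)
    )


def read_trajectory(csv_path, events_path=None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    The dense interpolants are not serialized, so the returned trajectory
    supports grid-based summaries but not :meth:`Trajectory.eval`.
    """
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trajectory CSV {csv_path}: {exc}") from exc
    if list(df.columns) != list(_CSV_HEADER):
        raise ValueError(
            f"trajectory CSV {csv_path} has columns {list(df.columns)}, expected {list(_CSV_HEADER)}"
        )
    events_path = Path(events_path) if events_path else csv_path.with_suffix(".events.json")
    events: list[tuple[float, float]] = []
    if events_path.exists():
        doc = json.loads(events_path.read_text())
        events = [(e["time"], e["jump"]) for e in doc.get("events", [])]
    arr = df.to_numpy(dtype=float)
    return Trajectory(times=arr[:, 0], states=arr[:, 1:], events=events, segments=[])
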