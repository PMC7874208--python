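"""File formats: trace CSV, per-cycle CSV, trial JSON, YAML configs.

The trace CSV is the interchange format between tracking and analysis:
one row per recorded frame with columns ``frame_index``, ``time_s``,
``tail_angle_deg``, ``is_black_frame`` plus an ``epoch`` membership column.
Rest periods contain no frames; they appear as gaps in ``time_s``.  Files
without the epoch column are accepted: epochs are then reconstructed from
the time gaps (a jump larger than 1.5 frame intervals starts a new epoch,
and the excess is the rest duration), which recovers everything except
boundaries between back-to-back epochs with zero rest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synth import EpochSpan, PhenotypeParams, StimulusProtocol, TailTrace, phenotype_preset

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_cycles_csv",
    "read_cycles_csv",
    "write_trial_json",
    "load_config",
    "protocol_from_config",
    "params_from_config",
]

_TRACE_COLUMNS = ["frame_index", "time_s", "tail_angle_deg", "is_black_frame"]


def write_trace_csv(trace: TailTrace, path: str | Path) -> Path:
    path = Path(path)
    epoch_col = np.zeros(trace.n_frames, dtype=int)
    for e, ep in enumerate(trace.epoch_spans()):
        epoch_col[ep.start : ep.stop] = e
    df = pd.DataFrame(
        {
            "frame_index": np.arange(trace.n_frames),
            "time_s": trace.times(),
            "tail_angle_deg": trace.angles,
            "is_black_frame": np.isin(
                np.arange(trace.n_frames), trace.black_frames
            ).astype(int),
            # extra column: epoch membership survives even zero-length rests
            "epoch": epoch_col,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_trace_csv(path: str | Path, fps: float | None = None) -> TailTrace:
    """Load a trace CSV, reconstructing epoch boundaries from time gaps."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace file: {path}")
    df = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} lacks columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if fps is None:
        dt = np.diff(t)
        fps = 1.0 / float(np.median(dt)) if len(dt) else 30.0
        if abs(fps - round(fps)) < 0.01:  # undo %.6f rounding of time_s
            fps = float(round(fps))
    frame_dt = 1.0 / fps

    if "epoch" in df.columns:
        e = df["epoch"].to_numpy(dtype=int)
        breaks = np.flatnonzero(np.diff(e) != 0) + 1
    else:
        # Epoch boundaries: a time step exceeding 1.5 frame intervals.
        breaks = np.flatnonzero(np.diff(t) > 1.5 * frame_dt) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [len(t)]])
    epochs = []
    for i, (s, e) in enumerate(zip(starts, stops)):
        rest = 0.0
        if i < len(starts) - 1:
            rest = max(0.0, float(t[stops[i]] - t[stops[i] - 1] - frame_dt))
        epochs.append(EpochSpan(int(s), int(e), float(t[s]), rest))

    blacks = np.flatnonzero(df["is_black_frame"].to_numpy(dtype=int) == 1)
    valid = np.ones(len(t), dtype=bool)
    valid[blacks] = False
    return TailTrace(
        angles=df["tail_angle_deg"].to_numpy(dtype=float),
        fps=float(round(fps, 6)),
        black_frames=blacks,
        valid=valid,
        meta={"source": str(path)},
        epochs=epochs,
    )


def write_cycles_csv(cycles: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cycles.to_csv(path, index=False, float_format="%.6f")
    return path


def read_cycles_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cycles file: {path}")
    return pd.read_csv(path)


def write_trial_json(trial, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(trial.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def protocol_from_config(cfg: dict[str, Any] | None) -> StimulusProtocol:
    """Build a protocol from a config mapping.

    Accepts the StimulusProtocol field names plus a ``kind`` shortcut:
    ``standard`` (default), ``prolonged`` or ``defined_interval``.
    """
    cfg = dict(cfg or {})
    kind = cfg.pop("kind", "standard")
    if "epochs" in cfg and cfg["epochs"] is not None:
        cfg["epochs"] = tuple(tuple(e) for e in cfg["epochs"])
    if kind == "standard":
        return StimulusProtocol(**cfg)
    if kind == "prolonged":
        return StimulusProtocol.prolonged(**cfg)
    if kind == "defined_interval":
        return StimulusProtocol.defined_interval(**cfg)
    raise ValueError(f"unknown protocol kind {kind!r}")


def params_from_config(cfg: dict[str, Any] | None) -> PhenotypeParams:
    """Build phenotype parameters from a config mapping.

    ``preset`` selects a named phenotype class; remaining keys override
    individual fields.
    """
    cfg = dict(cfg or {})
    preset = cfg.pop("preset", None)
    if preset is not None:
        return phenotype_preset(preset, **cfg)
    return PhenotypeParams(**cfg)
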