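"""Readers and writers for trial logs, gaze streams, synchrony tables and
model traces.

All tables are UTF-8 comma-separated with a header row and "." decimals.
Timestamps are seconds relative to trial onset.  Trial logs carry one
session per file; gaze streams key rows by (participant_id, trial_id,
phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelConfig, TrialRecord
from .synchrony import GazeSeries, SynchronyIndex

__all__ = [
    "TrialLogError",
    "MissingColumnError",
    "InvalidTouchCodeError",
    "ReactionTimeError",
    "RunConfig",
    "read_trial_log",
    "write_trial_log",
    "read_gaze_stream",
    "write_gaze_streams",
    "read_synchrony_table",
    "write_synchrony_table",
    "read_trace",
    "write_trace",
    "load_run_config",
]

logger = logging.getLogger("dyadinfer")

TRIAL_COLUMNS = [
    "trial_index", "object_id", "category", "difficulty",
    "handle_side", "touch", "correct", "reaction_time",
]
GAZE_COLUMNS = ["participant_id", "trial_id", "phase", "t", "x", "y", "z"]


class TrialLogError(ValueError):
    """Base class for trial-log validation failures."""


class MissingColumnError(TrialLogError):
    """A required column is absent from the header."""


class InvalidTouchCodeError(TrialLogError):
    """A touch outcome outside {1, -1, 0}."""


class ReactionTimeError(TrialLogError):
    """A reaction time outside [0, 3] seconds."""


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read and validate one session's trial log."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        touch = row["touch"]
        if touch not in (1, -1, 0):
            raise InvalidTouchCodeError(
                f"{path}: trial {row['trial_index']}: touch code {touch!r} "
                "not in {1, -1, 0}"
            )
        rt = float(row["reaction_time"])
        if not 0.0 <= rt <= 3.0:
            raise ReactionTimeError(
                f"{path}: trial {row['trial_index']}: reaction_time {rt} "
                "outside [0, 3] s"
            )
        records.append(TrialRecord(
            trial_index=int(row["trial_index"]),
            object_id=str(row["object_id"]),
            category=str(row["category"]),
            difficulty=int(row["difficulty"]),
            handle_side=str(row["handle_side"]),
            touch_outcome=int(touch),
            correct=int(row["correct"]),
            reaction_time=rt,
        ))
    return records


def write_trial_log(records: list[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame([{
        "trial_index": r.trial_index,
        "object_id": r.object_id,
        "category": r.category,
        "difficulty": r.difficulty,
        "handle_side": r.handle_side,
        "touch": r.touch_outcome,
        "correct": r.correct,
        "reaction_time": r.reaction_time,
    } for r in records], columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def read_gaze_stream(path: str | Path) -> tuple[dict, int]:
    """Read gaze samples grouped by (participant_id, trial_id, phase).

    Rows with any missing coordinate or timestamp are dropped; the dropped
    count is returned alongside the series dictionary.  Non-monotone
    timestamps within a series raise ``ValueError``.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("gaze stream %s is empty", path)
        return {}, 0
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    n_before = len(df)
    df = df.dropna(subset=["t", "x", "y", "z"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d incomplete gaze rows from %s", n_dropped, path)
    series: dict = {}
    for (pid, tid, phase), grp in df.groupby(["participant_id", "trial_id", "phase"],
                                             sort=True):
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"{path}: non-monotone timestamps for participant {pid!r}, "
                f"trial {tid}, phase {phase!r}"
            )
        xyz = grp[["x", "y", "z"]].to_numpy(dtype=float)
        series[(str(pid), int(tid), str(phase))] = GazeSeries(
            str(pid), int(tid), t, xyz, str(phase))
    return series, n_dropped


def write_gaze_streams(pairs: dict[int, tuple[GazeSeries, GazeSeries]],
                       path: str | Path) -> None:
    """Write per-trial paired gaze streams as one long-format CSV.

    NaN coordinates (simulated dropouts) are written as empty fields, which
    the reader drops and counts.
    """
    frames = []
    for tid in sorted(pairs):
        for s in pairs[tid]:
            frames.append(pd.DataFrame({
                "participant_id": s.participant_id,
                "trial_id": tid,
                "phase": s.phase,
                "t": s.t,
                "x": s.xyz[:, 0],
                "y": s.xyz[:, 1],
                "z": s.xyz[:, 2],
            }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=GAZE_COLUMNS))
    df.to_csv(path, index=False)


def write_synchrony_table(indices: list[SynchronyIndex], path: str | Path) -> None:
    pd.DataFrame([{
        "trial_id": s.trial_id,
        "dtw_raw": s.dtw_raw,
        "dtw_norm": s.dtw_norm,
        "xcorr": s.xcorr,
        "gamma_t": s.gamma_t,
    } for s in indices]).to_csv(path, index=False)


def read_synchrony_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["trial_id", "dtw_norm", "gamma_t"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")
    return df


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    trace.to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Run-level configuration assembled from a YAML file plus defaults."""

    model: ModelConfig = field(default_factory=ModelConfig)
    gamma0_grid: tuple[float, ...] = (0.0, 0.1, 0.5, 0.9)
    session_type: str = "bot_pair"
    seed: int = 0
    rho: float | None = None
    noise: float = 0.05
    hard_touch_prob: float = 0.5
    hard_only: bool = True

    def __post_init__(self) -> None:
        for g in self.gamma0_grid:
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"gamma0 grid value {g} outside [0, 1]")


def load_run_config(path: str | Path | None) -> RunConfig:
    """Build a RunConfig from a YAML file; ``None`` yields defaults.

    The file may carry a ``model:`` block with ModelConfig fields and
    top-level keys for the remaining RunConfig fields.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_kwargs = raw.pop("model", {}) or {}
    if "gamma0_grid" in raw:
        raw["gamma0_grid"] = tuple(raw["gamma0_grid"])
    return RunConfig(model=ModelConfig(**model_kwargs), **raw)
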