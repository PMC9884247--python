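"""In-memory containers shared across the pipeline.

All time axes are integer-millisecond grids relative to pursuit-target
(stimulus) onset; directions are signed degrees with 0° = rightward and
negative angles rotating clockwise (downward on screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

VALID = "valid"
INVALID = "invalid"

#: feature kinds understood by the features / mvpa / linmodel modules
FEATURE_KINDS = ("eye_velocity", "eye_position", "retinal_velocity_error", "irve")


def _check_time_axis(time: np.ndarray) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time axis must be a 1-D array with >= 2 samples")
    steps = np.diff(time)
    if not np.allclose(steps, 1.0):
        raise ValueError("time axis must be strictly increasing with a uniform 1 ms step")
    return time


@dataclass
class EyeTrace:
    """One trial's 2-D eye position (deg) and velocity (deg/s) at 1 kHz."""

    time: np.ndarray
    pos_h: np.ndarray
    pos_v: np.ndarray
    vel_h: np.ndarray
    vel_v: np.ndarray
    target_direction: float
    cue_direction: float
    contrast: float
    block: str
    day: str = "day1"
    trial_id: str = "t0"
    latency_true: float | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.time = _check_time_axis(self.time)
        n = self.time.size
        for name in ("pos_h", "pos_v", "vel_h", "vel_v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        if self.block not in (VALID, INVALID):
            raise ValueError(f"block must be '{VALID}' or '{INVALID}', got {self.block!r}")

    def speed(self) -> np.ndarray:
        """Instantaneous eye speed, deg/s."""
        return np.hypot(self.vel_h, self.vel_v)

    def index_of(self, t_ms: float) -> int:
        idx = int(round(t_ms - self.time[0]))
        if not 0 <= idx < self.time.size:
            raise ValueError(f"time {t_ms} ms outside axis [{self.time[0]}, {self.time[-1]}]")
        return idx

    def shifted(self, dt_ms: float) -> "EyeTrace":
        """Copy with the time axis shifted by ``dt_ms`` (contents unchanged)."""
        return replace(self, time=self.time + dt_ms)


META_COLUMNS = ("trial_id", "target_direction", "cue_direction", "contrast", "block", "day")


def traces_meta(traces: Sequence[EyeTrace]) -> pd.DataFrame:
    """Tidy one-row-per-trial metadata table for a trace collection."""
    rows = [
        {
            "trial_id": tr.trial_id,
            "target_direction": tr.target_direction,
            "cue_direction": tr.cue_direction,
            "contrast": tr.contrast,
            "block": tr.block,
            "day": tr.day,
            "latency_true": np.nan if tr.latency_true is None else tr.latency_true,
        }
        for tr in traces
    ]
    return pd.DataFrame(rows)


@dataclass
class EpochSet:
    """trials x channels x time array with channel names and trial metadata."""

    data: np.ndarray
    channel_names: list[str]
    time: np.ndarray
    trial_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        self.time = _check_time_axis(self.time)
        self.channel_names = [str(c) for c in self.channel_names]
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channel_names):
            raise ValueError(f"{len(self.channel_names)} channel names for {n_ch} channels")
        if n_t != self.time.size:
            raise ValueError("time axis length does not match data")
        if len(self.trial_meta) != n_tr:
            raise ValueError("trial_meta rows must match trial count")
        if "day" not in self.trial_meta.columns:
            raise ValueError("trial_meta must carry a 'day' column")
        self.trial_meta = self.trial_meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def days(self) -> np.ndarray:
        return self.trial_meta["day"].to_numpy()

    def index_of(self, t_ms: float) -> int:
        idx = int(round(t_ms - self.time[0]))
        if not 0 <= idx < self.time.size:
            raise ValueError(f"time {t_ms} ms outside axis [{self.time[0]}, {self.time[-1]}]")
        return idx

    def subset_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return EpochSet(
            data=self.data[idx],
            channel_names=list(self.channel_names),
            time=self.time.copy(),
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
        )

    def select_trials(self, **conditions) -> "EpochSet":
        """Subset trials by equality on trial_meta columns, e.g. block='valid'."""
        mask = np.ones(self.n_trials, dtype=bool)
        for col, val in conditions.items():
            if col not in self.trial_meta.columns:
                raise KeyError(f"no metadata column {col!r}")
            colvals = self.trial_meta[col].to_numpy()
            if np.issubdtype(np.asarray(colvals).dtype, np.number):
                mask &= np.isclose(colvals.astype(float), float(val))
            else:
                mask &= colvals == val
        return self.subset_trials(mask)


@dataclass
class FeatureTrace:
    """Per-trial 2-D (horizontal, vertical) time series of one feature kind."""

    kind: str
    time: np.ndarray
    h: np.ndarray
    v: np.ndarray
    trial_id: str = "t0"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        self.time = _check_time_axis(self.time)
        for name in ("h", "v"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} must match the time axis")
            setattr(self, name, arr)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.h, self.v)

    def index_of(self, t_ms: float) -> int:
        idx = int(round(t_ms - self.time[0]))
        if not 0 <= idx < self.time.size:
            raise ValueError(f"time {t_ms} ms outside axis [{self.time[0]}, {self.time[-1]}]")
        return idx


@dataclass
class DissimilarityTrace:
    """Cross-validated Mahalanobis dissimilarity time course (D12 - D11)."""

    time: np.ndarray
    value: np.ndarray
    condition_pair: tuple = ("cond1", "cond2")
    slice_label: str = ""
    n_trials_used: tuple = (0, 0)
    subsample_iterations: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = _check_time_axis(self.time)
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.time.shape:
            raise ValueError("value must match the time axis")

    def index_of(self, t_ms: float) -> int:
        idx = int(round(t_ms - self.time[0]))
        if not 0 <= idx < self.time.size:
            raise ValueError(f"time {t_ms} ms outside axis [{self.time[0]}, {self.time[-1]}]")
        return idx
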