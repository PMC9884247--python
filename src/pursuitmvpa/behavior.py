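"""Saccade screening, pursuit-latency estimation, and rotated-trace distances.

The cue-attraction effect is quantified geometrically: every trial's
velocity trace is expressed in a coordinate frame rotated by -30 deg, which
maps the central target direction onto the horizontal axis and symmetrizes
the outer directions (0 and -60 deg) about it. The vertical separation
between the mean rotated traces of the upper and lower direction groups
(delta-y) then measures direction discrimination in the behavior, and the
valid-minus-invalid difference of that separation (delta-delta-y) measures
how much the cue pulled the invalid-block traces together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import INVALID, VALID, EyeTrace

logger = logging.getLogger(__name__)

FIXATION_WINDOW = (-100.0, 100.0)
PURSUIT_WINDOW = (100.0, 250.0)
FIXATION_THRESH = 5.0  # deg/s during fixation
PURSUIT_THRESH = 20.0  # deg/s during pursuit


@dataclass
class ScreeningReport:
    kept_trial_ids: list[str]
    rejected: list[tuple[str, str]]  # (trial_id, reason)
    thresholds: dict = field(default_factory=dict)

    @property
    def rejected_trial_ids(self) -> list[str]:
        return [tid for tid, _ in self.rejected]

    def kept_traces(self, traces: Sequence[EyeTrace]) -> list[EyeTrace]:
        kept = set(self.kept_trial_ids)
        return [tr for tr in traces if tr.trial_id in kept]


def _window_mask(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < time[0] or hi > time[-1]:
        raise ValueError(f"window {window} outside time axis [{time[0]}, {time[-1]}]")
    return (time >= lo) & (time <= hi)


def screen_saccades(
    traces: Sequence[EyeTrace],
    fixation_window: tuple[float, float] = FIXATION_WINDOW,
    pursuit_window: tuple[float, float] = PURSUIT_WINDOW,
    fixation_thresh: float = FIXATION_THRESH,
    pursuit_thresh: float = PURSUIT_THRESH,
) -> ScreeningReport:
    """Reject trials whose eye speed betrays a saccade.

    A trial is discarded if speed exceeds ``fixation_thresh`` anywhere in the
    fixation window or ``pursuit_thresh`` anywhere in the pursuit window;
    fixation violations take precedence in the reported reason.
    """
    kept: list[str] = []
    rejected: list[tuple[str, str]] = []
    for tr in traces:
        speed = tr.speed()
        fix = _window_mask(tr.time, fixation_window)
        pur = _window_mask(tr.time, pursuit_window)
        if np.any(speed[fix] > fixation_thresh):
            rejected.append((tr.trial_id, "fixation_speed"))
        elif np.any(speed[pur] > pursuit_thresh):
            rejected.append((tr.trial_id, "pursuit_speed"))
        else:
            kept.append(tr.trial_id)
    return ScreeningReport(
        kept_trial_ids=kept,
        rejected=rejected,
        thresholds={
            "fixation_window": tuple(fixation_window),
            "pursuit_window": tuple(pursuit_window),
            "fixation_thresh": fixation_thresh,
            "pursuit_thresh": pursuit_thresh,
        },
    )


def estimate_latency(
    trace: EyeTrace,
    baseline_window: tuple[float, float] = (-100.0, 0.0),
    search_window: tuple[float, float] = (50.0, 300.0),
    n_sd: float = 3.0,
    sustain_ms: int = 20,
    fallback_thresh: float = 2.0,
) -> float:
    """First time eye speed rises above baseline and stays there.

    Threshold = baseline mean + ``n_sd`` baseline SDs of speed; the crossing
    must persist for ``sustain_ms`` consecutive samples. From the first
    sustained crossing the estimate walks back to where speed last sat at
    baseline level (mean + 1 SD), so the reported latency is the movement
    onset rather than the threshold-crossing time. A flat baseline (zero
    variance) falls back to an absolute ``fallback_thresh`` deg/s.
    Returns NaN if no sustained crossing occurs.
    """
    if baseline_window[1] > search_window[0]:
        raise ValueError("baseline window must precede the search window")
    speed = trace.speed()
    base = speed[_window_mask(trace.time, baseline_window)]
    sd = float(np.std(base))
    if sd == 0.0:
        thresh = fallback_thresh
        logger.info("trial %s: degenerate baseline, absolute threshold %.1f deg/s",
                    trace.trial_id, fallback_thresh)
    else:
        thresh = float(np.mean(base)) + n_sd * sd
    search = _window_mask(trace.time, search_window)
    idx = np.flatnonzero(search)
    above = speed > thresh
    back_thresh = float(np.mean(base)) + (sd if sd > 0 else 0.0)
    run = 0
    for i in idx:
        run = run + 1 if above[i] else 0
        if run >= sustain_ms:
            j = i - sustain_ms + 1
            while j > 0 and speed[j - 1] > back_thresh:
                j -= 1
            return float(trace.time[j])
    return float("nan")


def rotate_velocity(vel_h: np.ndarray, vel_v: np.ndarray, rotation_deg: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Express velocity components in a frame rotated by ``rotation_deg``.

    A vector pointing along ``rotation_deg`` becomes purely horizontal.
    """
    rho = math.radians(rotation_deg)
    h = vel_h * math.cos(rho) + vel_v * math.sin(rho)
    v = -vel_h * math.sin(rho) + vel_v * math.cos(rho)
    return h, v


@dataclass
class TraceDistanceResult:
    """Rotated-trace separation, per block, with the cue-validity contrast."""

    time: np.ndarray  # ms, relative to latency (align='latency') or stimulus onset
    delta_y: dict  # block -> |mean upper - mean lower| rotated-vertical trace
    delta_delta_y: np.ndarray | None  # valid - invalid, when both blocks present
    value_at_100ms: float | None
    align: str = "latency"
    mean_latency: dict = field(default_factory=dict)  # block -> ms


def _group_mean_rotated_v(traces: list[EyeTrace], rotation: float, metric: str
                          ) -> tuple[np.ndarray, np.ndarray]:
    vs = []
    hs = []
    for tr in traces:
        h, v = rotate_velocity(tr.vel_h, tr.vel_v, rotation)
        hs.append(h)
        vs.append(v)
    return np.mean(hs, axis=0), np.mean(vs, axis=0)


def rotate_and_distance(
    traces: Sequence[EyeTrace],
    rotation: float = -30.0,
    upper_dir: float = 0.0,
    lower_dir: float = -60.0,
    align: str = "latency",
    metric: str = "vertical",
    align_window: tuple[float, float] = (-100.0, 100.0),
) -> TraceDistanceResult:
    """Distance between mean rotated upper- and lower-direction traces.

    ``metric='vertical'`` (default) measures the absolute vertical separation
    of the mean rotated traces; ``'euclidean'`` uses the full 2-D distance.
    With ``align='latency'`` each block's traces are re-timed to the block's
    mean estimated pursuit latency and sampled on ``align_window``; with
    ``align='stimulus'`` the native axis is kept. When both validity blocks
    are present, the valid-minus-invalid separation difference
    (delta-delta-y) and its value at +100 ms are also reported.
    """
    if align not in ("latency", "stimulus"):
        raise ValueError("align must be 'latency' or 'stimulus'")
    if metric not in ("vertical", "euclidean"):
        raise ValueError("metric must be 'vertical' or 'euclidean'")
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    time = traces[0].time
    blocks = [b for b in (VALID, INVALID) if any(tr.block == b for tr in traces)]

    delta_y: dict[str, np.ndarray] = {}
    mean_latency: dict[str, float] = {}
    for block in blocks:
        groups = {}
        for name, d in (("upper", upper_dir), ("lower", lower_dir)):
            sel = [tr for tr in traces
                   if tr.block == block and math.isclose(tr.target_direction, d, abs_tol=1e-6)]
            if not sel:
                raise ValueError(f"empty condition cell: block={block}, direction={d}")
            groups[name] = sel
        mh_u, mv_u = _group_mean_rotated_v(groups["upper"], rotation, metric)
        mh_l, mv_l = _group_mean_rotated_v(groups["lower"], rotation, metric)
        if metric == "vertical":
            dist = np.abs(mv_u - mv_l)
        else:
            dist = np.hypot(mh_u - mh_l, mv_u - mv_l)

        if align == "latency":
            lats = [estimate_latency(tr) for tr in groups["upper"] + groups["lower"]]
            lats = [l for l in lats if np.isfinite(l)]
            if not lats:
                raise ValueError(f"no measurable latency in block {block}")
            lat = float(np.mean(lats))
            mean_latency[block] = lat
            tau = np.arange(align_window[0], align_window[1] + 1.0)
            i0 = int(round(lat - time[0]))
            idx = i0 + (tau - 0.0).astype(int)
            if idx[0] < 0 or idx[-1] >= time.size:
                raise ValueError("alignment window falls outside the trace axis")
            delta_y[block] = dist[idx]
            out_time = tau
        else:
            delta_y[block] = dist
            out_time = time

    ddy = None
    value = None
    if VALID in delta_y and INVALID in delta_y:
        ddy = delta_y[VALID] - delta_y[INVALID]
        ref = ddy
    else:
        ref = delta_y[blocks[0]]
    if out_time[0] <= 100.0 <= out_time[-1]:
        value = float(ref[int(round(100.0 - out_time[0]))])
    return TraceDistanceResult(
        time=out_time,
        delta_y=delta_y,
        delta_delta_y=ddy,
        value_at_100ms=value,
        align=align,
        mean_latency=mean_latency,
    )
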