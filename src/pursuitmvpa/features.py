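"""Sensory and motor feature traces derived from eye movements.

The sensory side of pursuit initiation is described by the retinal velocity
error (RVE) — target velocity vector minus eye velocity vector, i.e. the
motion signal actually present on the retina — and by its running time
integral (IRVE), a position-dimensioned accumulation of uncorrected motion
error. The motor side is the eye velocity and eye position themselves.

Units: velocities in deg/s, positions and IRVE in deg; the time axis is in
ms, so integration uses dt = 1e-3 s per sample.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .containers import EyeTrace, FeatureTrace

MS_TO_S = 1e-3


def retinal_velocity_error(
    trace: EyeTrace,
    target_speed: float,
    target_direction: float | None = None,
    motion_onset: float = 0.0,
) -> FeatureTrace:
    """Target velocity vector minus eye velocity vector.

    Before ``motion_onset`` the target is stationary, so the RVE is simply
    the negated eye velocity; from onset on, the target moves at constant
    ``target_speed`` along ``target_direction`` (defaults to the trace's
    own target direction).
    """
    if target_direction is None:
        target_direction = trace.target_direction
    trace.index_of(motion_onset)  # range check
    theta = math.radians(target_direction)
    tvel_h = np.where(trace.time >= motion_onset, target_speed * math.cos(theta), 0.0)
    tvel_v = np.where(trace.time >= motion_onset, target_speed * math.sin(theta), 0.0)
    return FeatureTrace(
        kind="retinal_velocity_error",
        time=trace.time.copy(),
        h=tvel_h - trace.vel_h,
        v=tvel_v - trace.vel_v,
        trial_id=trace.trial_id,
    )


def integrate_rve(rve: FeatureTrace, start: float = 0.0) -> FeatureTrace:
    """Cumulative trapezoidal integral of the RVE from ``start`` (deg).

    The integral is zero at ``start`` and identically zero before it; the
    1 ms sampling makes the trapezoid rule essentially exact for the smooth
    ramps handled here.
    """
    if rve.kind != "retinal_velocity_error":
        raise ValueError(f"expected a retinal_velocity_error trace, got kind={rve.kind!r}")
    i0 = rve.index_of(start)
    out_h = np.zeros_like(rve.h)
    out_v = np.zeros_like(rve.v)
    out_h[i0:] = cumulative_trapezoid(rve.h[i0:], dx=MS_TO_S, initial=0.0)
    out_v[i0:] = cumulative_trapezoid(rve.v[i0:], dx=MS_TO_S, initial=0.0)
    return FeatureTrace(kind="irve", time=rve.time.copy(), h=out_h, v=out_v, trial_id=rve.trial_id)


def motor_features(trace: EyeTrace) -> tuple[FeatureTrace, FeatureTrace]:
    """Eye-velocity and eye-position feature traces for one trial."""
    vel = FeatureTrace(
        kind="eye_velocity",
        time=trace.time.copy(),
        h=trace.vel_h.copy(),
        v=trace.vel_v.copy(),
        trial_id=trace.trial_id,
    )
    pos = FeatureTrace(
        kind="eye_position",
        time=trace.time.copy(),
        h=trace.pos_h.copy(),
        v=trace.pos_v.copy(),
        trial_id=trace.trial_id,
    )
    return vel, pos


def feature_for_trial(trace: EyeTrace, kind: str, target_speed: float = 16.0,
                      motion_onset: float = 0.0, integrate_start: float = 0.0) -> FeatureTrace:
    """Convenience dispatch from a feature kind name to its trace."""
    if kind == "eye_velocity":
        return motor_features(trace)[0]
    if kind == "eye_position":
        return motor_features(trace)[1]
    rve = retinal_velocity_error(trace, target_speed=target_speed, motion_onset=motion_onset)
    if kind == "retinal_velocity_error":
        return rve
    if kind == "irve":
        return integrate_rve(rve, start=integrate_start)
    raise ValueError(f"unknown feature kind {kind!r}")
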