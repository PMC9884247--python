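"""Self-contained validation studies for the pipeline's statistical claims.

Each function runs one calibration or recovery study end to end at a stated
problem size and returns the measured quantities. They are used both by the
test suite and by the acceptance script, so every reported number is
recomputed from scratch on demand.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import linmodel
from .behavior import rotate_and_distance, screen_saccades
from .containers import INVALID, VALID
from .features import feature_for_trial, integrate_rve, retinal_velocity_error
from .mvpa import dissimilarity_arrays
from .stats import cluster_test
from .synth import SimulationConfig, generate_eye_traces

CONDITIONS = [(VALID, 1.0), (INVALID, 1.0), (VALID, 0.12), (INVALID, 0.12)]
TRUE_SHIFTS = (-35.0, 27.0)  # ms; sensory leads, motor lags the neural trace
TRUE_WEIGHTS = (1.0, 0.5)


def null_calibration(n_datasets: int = 200, n_trials: int = 100, n_channels: int = 4,
                     n_time: int = 20, seed: int = 0) -> dict:
    """Mean cross-validated dissimilarity over exchangeable condition pairs.

    Both conditions are drawn from one Gaussian, so the expected D12 - D11
    is zero; returns the across-dataset mean of the time-averaged value,
    its Monte-Carlo standard error, and their ratio.
    """
    rng = np.random.default_rng(seed)
    means = np.empty(n_datasets)
    for k in range(n_datasets):
        xa = rng.normal(size=(n_trials, n_channels, n_time))
        xb = rng.normal(size=(n_trials, n_channels, n_time))
        means[k] = dissimilarity_arrays(xa, xb).mean()
    mean = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(n_datasets))
    return {"mean": mean, "se": se, "z": mean / se, "n": n_datasets}


def _condition_separation_curves(seed: int = 42, n_trials_per_cell: int = 12
                                 ) -> tuple[dict, dict, np.ndarray]:
    """Noise-free per-condition IRVE and eye-velocity separation magnitudes.

    The Euclidean separation between the mean feature traces of the 0 and
    -60 deg direction groups, per condition cell; on noise-free traces this
    is the analytic counterpart of the trial-resampled dissimilarity.
    """
    cfg = SimulationConfig(n_trials_per_cell=n_trials_per_cell, n_channels=4,
                           noise_sd=0.0, latency_jitter_sd=0.0, saccade_rate=0.0,
                           seed=seed)
    traces = generate_eye_traces(cfg)
    sens, mot = {}, {}
    for block, contrast in CONDITIONS:
        sel = [t for t in traces
               if t.block == block and np.isclose(t.contrast, contrast)]

        def mean_feature(kind, direction):
            fs = [feature_for_trial(t, kind) for t in sel
                  if np.isclose(t.target_direction, direction)]
            return (np.mean([f.h for f in fs], axis=0),
                    np.mean([f.v for f in fs], axis=0))

        iu, il = mean_feature("irve", 0.0), mean_feature("irve", -60.0)
        vu, vl = mean_feature("eye_velocity", 0.0), mean_feature("eye_velocity", -60.0)
        sens[(block, contrast)] = np.hypot(iu[0] - il[0], iu[1] - il[1])
        mot[(block, contrast)] = np.hypot(vu[0] - vl[0], vu[1] - vl[1])
    return sens, mot, cfg.time_axis()


def _normalize_jointly(per_cond: dict) -> dict:
    allv = np.concatenate(list(per_cond.values()))
    lo, hi = float(allv.min()), float(allv.max())
    return {c: (v - lo) / (hi - lo) for c, v in per_cond.items()}


def _shift(sig: np.ndarray, s: int) -> np.ndarray:
    idx = np.clip(np.arange(sig.size) + int(s), 0, sig.size - 1)
    return sig[idx]


def shift_recovery_study(n_seeds: int = 100, noise_frac: float = 0.25,
                         seed: int = 0, window: tuple = (30.0, 330.0),
                         shift_bounds: tuple = (-100, 100)) -> dict:
    """Monte-Carlo recovery of the linear model's shifts and weights.

    Neural traces are generated as w_s * S(t + t_s) + w_m * M(t + t_m) from
    the normalized noise-free separation curves, with white noise at
    ``noise_frac`` of the signal SD; the grid fit is scored over
    ``n_seeds`` replicates. Also reports the noiseless fit.
    """
    sens, mot, time = _condition_separation_curves()
    n_s = _normalize_jointly(sens)
    n_m = _normalize_jointly(mot)
    w_s, w_m = TRUE_WEIGHTS
    t_s, t_m = TRUE_SHIFTS
    clean = {c: w_s * _shift(n_s[c], int(t_s)) + w_m * _shift(n_m[c], int(t_m))
             for c in CONDITIONS}
    i0 = int(window[0] - time[0])
    i1 = int(window[1] - time[0])
    signal_sd = float(np.concatenate(
        [clean[c][i0:i1 + 1] for c in CONDITIONS]).std())

    regs = {"irve": sens, "eye_velocity": mot}
    design0 = linmodel.build_design(clean, regs, window=window, time=time)
    fit0 = linmodel.fit(design0, shift_bounds=shift_bounds)

    rng = np.random.default_rng(seed)
    ts_hat, tm_hat, ws_err, wm_err = [], [], [], []
    for _ in range(n_seeds):
        noisy = {c: clean[c] + noise_frac * signal_sd * rng.normal(size=time.size)
                 for c in CONDITIONS}
        design = linmodel.build_design(noisy, regs, window=window, time=time)
        f = linmodel.fit(design, shift_bounds=shift_bounds)
        ts_hat.append(f.t_s)
        tm_hat.append(f.t_m)
        ws_err.append(abs(f.weights["irve"] - w_s) / w_s * 100.0)
        wm_err.append(abs(f.weights["eye_velocity"] - w_m) / w_m * 100.0)
    return {
        "median_t_s": float(np.median(ts_hat)),
        "median_t_m": float(np.median(tm_hat)),
        "median_abs_t_s_error": float(np.median(np.abs(np.array(ts_hat) - t_s))),
        "median_abs_t_m_error": float(np.median(np.abs(np.array(tm_hat) - t_m))),
        "median_ws_relative_error_pct": float(np.median(ws_err)),
        "median_wm_relative_error_pct": float(np.median(wm_err)),
        "noiseless_t_s": fit0.t_s,
        "noiseless_t_m": fit0.t_m,
        "noiseless_r_squared": fit0.r_squared,
        "noiseless_rss": fit0.rss,
        "n": n_seeds,
    }


def cluster_fwer_study(n_reps: int = 500, n_participants: int = 14,
                       n_time: int = 60, threshold_p: float = 0.05,
                       n_perm: int = 1000, seed: int = 0) -> dict:
    """Family-wise false-positive rate of the cluster test under the null."""
    rng = np.random.default_rng(seed)
    false_positives = 0
    for rep in range(n_reps):
        x = rng.normal(size=(n_participants, n_time))
        res = cluster_test(x, threshold_p=threshold_p, n_perm=n_perm,
                           seed=int(rng.integers(2 ** 31 - 1)))
        if any(c.p < 0.05 for c in res.clusters):
            false_positives += 1
    return {"fwer": false_positives / n_reps, "n": n_reps}


def cluster_power_study(n_reps: int = 200, n_participants: int = 14,
                        n_time: int = 150, effect_window: tuple = (50, 100),
                        effect_sd: float = 1.0, threshold_p: float = 0.05,
                        n_perm: int = 1000, seed: int = 0) -> dict:
    """Detection rate for a boxcar effect injected across participants.

    A hit requires a significant cluster overlapping the injection window.
    """
    rng = np.random.default_rng(seed)
    lo, hi = effect_window
    hits = 0
    for rep in range(n_reps):
        x = rng.normal(size=(n_participants, n_time))
        x[:, lo:hi + 1] += effect_sd
        res = cluster_test(x, threshold_p=threshold_p, n_perm=n_perm,
                           seed=int(rng.integers(2 ** 31 - 1)))
        if any(c.p < 0.05 and c.start_ms <= hi and c.end_ms >= lo
               for c in res.clusters):
            hits += 1
    return {"power": hits / n_reps, "n": n_reps}


def cue_effect_study(n_trials_per_cell: int = 200, seed: int = 0) -> dict:
    """Delta-delta-y at +100 ms post latency per contrast on generated data.

    With target reliability lower at 12% than 100% contrast, the cue pulls
    invalid-block traces together more strongly at low contrast, so the
    valid-minus-invalid separation difference should be larger there.
    """
    cfg = SimulationConfig(n_trials_per_cell=n_trials_per_cell, n_channels=4,
                           saccade_rate=0.05, seed=seed)
    traces = generate_eye_traces(cfg)
    kept = screen_saccades(traces).kept_traces(traces)
    out = {}
    for contrast in (1.0, 0.12):
        sel = [t for t in kept if np.isclose(t.contrast, contrast)]
        res = rotate_and_distance(sel)
        out[contrast] = float(res.value_at_100ms)
    return {"ddy_high_contrast": out[1.0], "ddy_low_contrast": out[0.12],
            "n": n_trials_per_cell}


def irve_rise_after_velocity_plateau(late_window: tuple = (350.0, 500.0)) -> dict:
    """Late-window growth of the IRVE vs eye-velocity separation curves.

    On noise-free traces the velocity separation saturates once both ramps
    reach target speed, while the IRVE separation — the integral of a
    plateaued difference — keeps growing. Growth is expressed as the rise
    over the late window relative to each curve's maximum.
    """
    sens, mot, time = _condition_separation_curves()
    s = sens[(VALID, 1.0)]
    m = mot[(VALID, 1.0)]
    i0 = int(late_window[0] - time[0])
    i1 = int(late_window[1] - time[0])
    return {
        "irve_late_rise_frac": float((s[i1] - s[i0]) / s.max()),
        "velocity_late_rise_frac": float((m[i1] - m[i0]) / m.max()),
    }


def irve_constant_ramp_value(target_speed: float = 16.0, at_ms: float = 200.0) -> float:
    """IRVE horizontal component for an untracked constant-velocity target."""
    time = np.arange(-100.0, 501.0)
    from .containers import EyeTrace
    zeros = np.zeros_like(time)
    tr = EyeTrace(time=time, pos_h=zeros, pos_v=zeros, vel_h=zeros, vel_v=zeros,
                  target_direction=0.0, cue_direction=0.0, contrast=1.0,
                  block=VALID)
    rve = retinal_velocity_error(tr, target_speed, target_direction=0.0)
    irve = integrate_rve(rve, start=0.0)
    return float(irve.h[irve.index_of(at_ms)])


def residual_injection_study(noise_sd: float = 0.01, bump_amp: float = 0.4,
                             bump_center: float = 110.0, bump_sd: float = 10.0,
                             seed: int = 5) -> dict:
    """Recovery of an injected pre-initiation validity effect from residuals.

    A Gaussian bump is added to the low-contrast valid condition's neural
    trace only; after fitting the reduced model, the valid-minus-invalid
    residual difference should carry the bump's sign inside its window and
    stay near zero outside.
    """
    sens, mot, time = _condition_separation_curves()
    n_s = _normalize_jointly(sens)
    n_m = _normalize_jointly(mot)
    w_s, w_m = TRUE_WEIGHTS
    t_s, t_m = TRUE_SHIFTS
    rng = np.random.default_rng(seed)
    neural = {c: w_s * _shift(n_s[c], int(t_s)) + w_m * _shift(n_m[c], int(t_m))
              + noise_sd * rng.normal(size=time.size) for c in CONDITIONS}
    bump = bump_amp * np.exp(-0.5 * ((time - bump_center) / bump_sd) ** 2)
    neural[(VALID, 0.12)] = neural[(VALID, 0.12)] + bump

    design = linmodel.build_design(neural, {"irve": sens, "eye_velocity": mot},
                                   window=(30.0, 330.0), time=time)
    f = linmodel.fit(design, shift_bounds=(-60, 60))
    _, diffs = linmodel.residual_analysis(f)
    fit_time = np.arange(30.0, 331.0)
    inside = (fit_time >= bump_center - 2 * bump_sd) & (fit_time <= bump_center + 2 * bump_sd)
    diff = diffs[0.12]
    return {
        "inside_mean": float(diff[inside].mean()),
        "outside_mean": float(diff[~inside].mean()),
        "window": (float(bump_center - 2 * bump_sd), float(bump_center + 2 * bump_sd)),
    }
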