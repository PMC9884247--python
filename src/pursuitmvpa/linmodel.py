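"""Time-shifted linear model of neural dissimilarity.

The neural dissimilarity time course E(t) is modelled as a weighted sum of
time-shifted sensory and motor dissimilarity regressors,

    E(t) = w_s * S_irve(t + t_s) + w_m * M_vel(t + t_m)          (reduced)

with a negative t_s meaning the sensory signal leads the neural one. The
full variant adds the retinal-velocity-error dissimilarity (sharing t_s)
and the eye-position dissimilarity (sharing t_m), for six free parameters
in total. All four experimental conditions (cue validity x contrast) are
fitted simultaneously with a single parameter set.

Because the weights enter linearly, they are profiled out in closed form by
ordinary least squares at each candidate (t_s, t_m) pair; an exhaustive
integer-millisecond grid over the shift bounds then finds the global
optimum deterministically. A seeded multistart hill-climb is available as
an alternative search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import DissimilarityTrace

logger = logging.getLogger(__name__)

SENSORY_KINDS = ("irve", "retinal_velocity_error")
MOTOR_KINDS = ("eye_velocity", "eye_position")
REDUCED_KINDS = ("irve", "eye_velocity")
FULL_KINDS = ("irve", "retinal_velocity_error", "eye_velocity", "eye_position")


def _as_array(trace, n: int | None = None) -> np.ndarray:
    if isinstance(trace, DissimilarityTrace):
        return np.asarray(trace.value, dtype=float)
    return np.asarray(trace, dtype=float)


@dataclass
class DesignBundle:
    """Aligned neural targets and max-min-normalized regressor traces."""

    time: np.ndarray  # common full ms axis
    window: tuple  # fit window in ms, inclusive
    conditions: list  # condition labels, fixed order
    y: np.ndarray  # concatenated neural values over the window
    y_by_cond: dict  # condition -> windowed neural trace
    regressors: dict  # kind -> condition -> full-axis normalized trace
    window_idx: np.ndarray  # indices of window samples in the full axis
    n_per_cond: int


def build_design(
    neural: Mapping,
    regressors: Mapping,
    window: tuple = (30.0, 330.0),
    time: np.ndarray | None = None,
) -> DesignBundle:
    """Assemble the fit design from per-condition dissimilarity traces.

    ``neural`` maps condition label -> DissimilarityTrace (or array);
    ``regressors`` maps feature kind -> {condition -> trace}. Each
    regressor kind is max-min normalized jointly across conditions and
    time points; the neural traces are left on their native scale.
    """
    conditions = list(neural.keys())
    if not conditions:
        raise ValueError("no conditions given")
    first = next(iter(neural.values()))
    if time is None:
        if not isinstance(first, DissimilarityTrace):
            raise ValueError("pass `time` explicitly when neural traces are raw arrays")
        time = first.time
    time = np.asarray(time, dtype=float)
    n_t = time.size

    lo, hi = window
    if lo < time[0] or hi > time[-1]:
        raise ValueError(f"window {window} outside axis [{time[0]}, {time[-1]}]")
    i0 = int(round(lo - time[0]))
    i1 = int(round(hi - time[0]))
    window_idx = np.arange(i0, i1 + 1)

    y_by_cond = {}
    for cond in conditions:
        arr = _as_array(neural[cond])
        if arr.size != n_t:
            raise ValueError(f"neural trace for {cond!r} does not match the time axis")
        y_by_cond[cond] = arr[window_idx].copy()
    y = np.concatenate([y_by_cond[c] for c in conditions])

    norm_reg: dict = {}
    for kind, per_cond in regressors.items():
        stack = {}
        for cond in conditions:
            if cond not in per_cond:
                raise ValueError(f"regressor {kind!r} missing condition {cond!r}")
            arr = _as_array(per_cond[cond])
            if arr.size != n_t:
                raise ValueError(f"regressor {kind!r}/{cond!r} does not match the time axis")
            stack[cond] = arr.astype(float)
        all_vals = np.concatenate(list(stack.values()))
        lo_v, hi_v = float(all_vals.min()), float(all_vals.max())
        rng_v = hi_v - lo_v
        if rng_v == 0.0:
            logger.info("regressor %r has zero range; normalized to all-zero", kind)
            norm_reg[kind] = {c: np.zeros(n_t) for c in conditions}
        else:
            norm_reg[kind] = {c: (stack[c] - lo_v) / rng_v for c in conditions}
    return DesignBundle(
        time=time, window=(float(lo), float(hi)), conditions=conditions,
        y=y, y_by_cond=y_by_cond, regressors=norm_reg,
        window_idx=window_idx, n_per_cond=window_idx.size,
    )


@dataclass
class LinearModelFit:
    weights: dict  # feature kind -> weight
    t_s: float
    t_m: float
    r_squared: float
    rss: float
    window: tuple
    variant: str
    conditions: list
    predictions: dict  # condition -> predicted windowed trace
    residuals: dict  # condition -> observed - predicted
    observed: dict  # condition -> observed windowed trace
    intercept: float | None = None
    search: dict = field(default_factory=dict)


def _variant_kinds(variant: str) -> tuple[list[str], list[str]]:
    if variant == "reduced":
        kinds = REDUCED_KINDS
    elif variant == "full":
        kinds = FULL_KINDS
    else:
        raise ValueError("variant must be 'reduced' or 'full'")
    sens = [k for k in kinds if k in SENSORY_KINDS]
    mot = [k for k in kinds if k in MOTOR_KINDS]
    return sens, mot


def _shift_columns(design: DesignBundle, kinds: Sequence[str], shifts: np.ndarray
                   ) -> np.ndarray:
    """Stacked regressor columns: (n_kinds, n_shifts, n_rows).

    Column value at row (cond, t) for shift s is the regressor at t + s.
    """
    n_t = design.time.size
    base = design.window_idx
    cols = np.empty((len(kinds), shifts.size, design.n_per_cond * len(design.conditions)))
    for ki, kind in enumerate(kinds):
        for si, s in enumerate(shifts):
            idx = base + int(s)
            if idx[0] < 0 or idx[-1] >= n_t:
                raise ValueError(
                    f"shift {s} ms needs axis coverage "
                    f"[{design.window[0] + s}, {design.window[1] + s}] ms")
            cols[ki, si] = np.concatenate(
                [design.regressors[kind][c][idx] for c in design.conditions])
    return cols


def _check_bounds(design: DesignBundle, shift_bounds: tuple) -> np.ndarray:
    lo, hi = int(shift_bounds[0]), int(shift_bounds[1])
    need_lo = design.window[0] + lo
    need_hi = design.window[1] + hi
    if need_lo < design.time[0] or need_hi > design.time[-1]:
        raise ValueError(
            f"shift bounds {shift_bounds} require axis coverage [{need_lo}, {need_hi}] ms; "
            f"available [{design.time[0]}, {design.time[-1]}] ms")
    return np.arange(lo, hi + 1)


def fit(
    design: DesignBundle,
    variant: str = "reduced",
    shift_bounds: tuple = (-100, 100),
    search: str = "grid",
    seed: int = 0,
    intercept: bool = False,
    n_starts: int = 50,
) -> LinearModelFit:
    """Estimate weights and shifts by profiled least squares.

    ``search='grid'`` scans every integer-ms (t_s, t_m) pair in
    ``shift_bounds`` (deterministic, global within bounds); ties in the
    residual sum of squares are broken toward the smallest |t_s| + |t_m|.
    ``search='multistart'`` runs a seeded hill-climb from ``n_starts``
    random shift pairs instead.
    """
    sens_kinds, mot_kinds = _variant_kinds(variant)
    shifts = _check_bounds(design, shift_bounds)
    y = design.y
    yy = float(y @ y)

    a_s = _shift_columns(design, sens_kinds, shifts)  # (ks, nS, R)
    a_m = _shift_columns(design, mot_kinds, shifts)  # (km, nT, R)
    ks, km = len(sens_kinds), len(mot_kinds)
    n_rows = y.size
    p = ks + km + (1 if intercept else 0)

    def rss_full_grid() -> tuple[np.ndarray, np.ndarray]:
        ss = np.einsum("ksr,lsr->skl", a_s, a_s)  # (nS, ks, ks)
        mm = np.einsum("kmr,lmr->mkl", a_m, a_m)  # (nT, km, km)
        sm = np.einsum("ksr,lmr->smkl", a_s, a_m)  # (nS, nT, ks, km)
        sy = np.einsum("ksr,r->sk", a_s, y)
        my = np.einsum("kmr,r->mk", a_m, y)
        n_s, n_m = shifts.size, shifts.size
        g = np.empty((n_s, n_m, p, p))
        b = np.empty((n_s, n_m, p))
        g[:, :, :ks, :ks] = ss[:, None]
        g[:, :, ks:ks + km, ks:ks + km] = mm[None, :]
        g[:, :, :ks, ks:ks + km] = sm
        g[:, :, ks:ks + km, :ks] = np.swapaxes(sm, 2, 3)
        b[:, :, :ks] = sy[:, None]
        b[:, :, ks:ks + km] = my[None, :]
        if intercept:
            cs = a_s.sum(axis=2)  # (ks, nS)
            cm = a_m.sum(axis=2)  # (km, nT)
            g[:, :, :ks, -1] = cs.T[:, None, :]
            g[:, :, -1, :ks] = cs.T[:, None, :]
            g[:, :, ks:ks + km, -1] = cm.T[None, :, :]
            g[:, :, -1, ks:ks + km] = cm.T[None, :, :]
            g[:, :, -1, -1] = n_rows
            b[:, :, -1] = float(y.sum())
        # least-norm solution handles collinear candidates
        beta = np.einsum("ijpq,ijq->ijp", np.linalg.pinv(g), b)
        rss = yy - np.einsum("ijp,ijp->ij", beta, b)
        return rss, beta

    def rss_at(i: int, j: int) -> float:
        x_cols = [a_s[k, i] for k in range(ks)] + [a_m[k, j] for k in range(km)]
        if intercept:
            x_cols.append(np.ones(n_rows))
        x = np.column_stack(x_cols)
        coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        return float(yy - coef @ (x.T @ y))

    if search == "grid":
        rss_grid, _ = rss_full_grid()
        best = _argmin_with_ties(rss_grid, shifts)
        search_record = {"mode": "grid", "n_candidates": int(rss_grid.size),
                         "bounds": (int(shifts[0]), int(shifts[-1]))}
    elif search == "multistart":
        rng = np.random.default_rng(seed)
        cache: dict[tuple[int, int], float] = {}

        def ev(i: int, j: int) -> float:
            if (i, j) not in cache:
                cache[(i, j)] = rss_at(i, j)
            return cache[(i, j)]

        n = shifts.size
        best_ij, best_rss = None, np.inf
        for _ in range(n_starts):
            i, j = int(rng.integers(n)), int(rng.integers(n))
            improved = True
            while improved:
                improved = False
                for step in (16, 8, 4, 2, 1):
                    for di, dj in ((step, 0), (-step, 0), (0, step), (0, -step),
                                   (step, step), (step, -step),
                                   (-step, step), (-step, -step)):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < n and 0 <= nj < n and ev(ni, nj) < ev(i, j) - 1e-14:
                            i, j = ni, nj
                            improved = True
            if ev(i, j) < best_rss:
                best_rss, best_ij = ev(i, j), (i, j)
        best = (best_ij[0], best_ij[1])
        search_record = {"mode": "multistart", "n_starts": n_starts,
                         "n_evaluations": len(cache), "seed": seed,
                         "bounds": (int(shifts[0]), int(shifts[-1]))}
    else:
        raise ValueError("search must be 'grid' or 'multistart'")

    i_best, j_best = best
    t_s, t_m = float(shifts[i_best]), float(shifts[j_best])
    x_cols = [a_s[k, i_best] for k in range(ks)] + [a_m[k, j_best] for k in range(km)]
    if intercept:
        x_cols.append(np.ones(n_rows))
    x = np.column_stack(x_cols)
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        logger.warning("collinear regressors at the optimum; least-norm weights returned")
    pred = x @ coef
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    weights = {k: float(coef[idx]) for idx, k in enumerate(list(sens_kinds) + list(mot_kinds))}
    npc = design.n_per_cond
    predictions, residuals, observed = {}, {}, {}
    for ci, cond in enumerate(design.conditions):
        sl = slice(ci * npc, (ci + 1) * npc)
        predictions[cond] = pred[sl].copy()
        observed[cond] = y[sl].copy()
        residuals[cond] = observed[cond] - predictions[cond]
    return LinearModelFit(
        weights=weights, t_s=t_s, t_m=t_m, r_squared=r2, rss=rss,
        window=design.window, variant=variant, conditions=list(design.conditions),
        predictions=predictions, residuals=residuals, observed=observed,
        intercept=float(coef[-1]) if intercept else None,
        search=search_record,
    )


def _argmin_with_ties(rss: np.ndarray, shifts: np.ndarray) -> tuple[int, int]:
    """Global minimum; near-ties resolved toward the smallest |t_s| + |t_m|."""
    min_val = float(np.min(rss))
    tol = 1e-9 * max(1.0, abs(min_val))
    ii, jj = np.nonzero(rss <= min_val + tol)
    cost = np.abs(shifts[ii]) + np.abs(shifts[jj])
    k = int(np.argmin(cost))
    return int(ii[k]), int(jj[k])


def residual_analysis(fit_result: LinearModelFit) -> tuple[dict, dict]:
    """Per-condition residual traces and valid-minus-invalid differences.

    Condition labels are expected to be (validity, contrast) tuples; the
    second return value maps each contrast to the valid - invalid residual
    difference on the fit window, ready for cluster-based testing.
    """
    residuals = {c: r.copy() for c, r in fit_result.residuals.items()}
    diffs: dict = {}
    by_key = {}
    for cond in fit_result.conditions:
        if isinstance(cond, tuple) and len(cond) == 2:
            validity, contrast = cond
            by_key.setdefault(contrast, {})[validity] = residuals[cond]
    for contrast, pair in by_key.items():
        if "valid" in pair and "invalid" in pair:
            diffs[contrast] = pair["valid"] - pair["invalid"]
    return residuals, diffs
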