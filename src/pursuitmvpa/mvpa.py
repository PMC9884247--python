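"""Cross-validated Mahalanobis dissimilarity of multivariate epochs.

For two condition trial sets the dissimilarity at each time point is
D12 - D11, where, with leave-one-trial-out cross-validation,

    D11 = mean_i sqrt( (TD1 - td1_i)^T pC+ (TD1 - td1_i) )
    D12 = mean_i sqrt( (TD2 - td1_i)^T pC+ (TD2 - td1_i) )

td1_i is the held-out trial's channel pattern, TD1 the mean of the
remaining own-condition trials, TD2 the mean of the other condition's
trials, and pC+ the pseudo-inverse of the pooled (optionally shrunk)
channel covariance. Because the held-out trial never enters its comparison
mean, D12 - D11 is centred on zero when the two conditions are
exchangeable, unlike the naive plug-in distance which is biased upward.

The same machinery applies unchanged to 2-D eye-movement features, with
the two "channels" being the horizontal and vertical components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.covariance import ledoit_wolf_shrinkage

from .containers import DissimilarityTrace, EpochSet, FeatureTrace
from .montage import CHANNEL_GROUPS

logger = logging.getLogger(__name__)


@dataclass
class PreprocessSpec:
    """Smoothing + normalization applied before distance computation."""

    smooth_halfwidth: int = 10  # ms; rectangular window of 2*hw+1 samples
    step: int = 1
    analysis_window: tuple = (-100.0, 500.0)
    day_max_normalize: bool = True
    channel_zscore: bool = True


def preprocess_epochs(epochs: EpochSet, spec: PreprocessSpec | None = None) -> EpochSet:
    """Rectangular smoothing, per-day max scaling, per-channel z-scoring.

    Smoothing averages each channel over +/- ``smooth_halfwidth`` ms (edges
    replicate the boundary sample). Each recording day is then divided by
    its global maximum absolute value so days with different amplifier
    scales are commensurate, and each channel is z-scored over all times
    and trials. Zero-variance channels are set to zero rather than NaN.
    """
    spec = spec or PreprocessSpec()
    data = epochs.data
    if spec.smooth_halfwidth > 0:
        data = uniform_filter1d(data, size=2 * spec.smooth_halfwidth + 1,
                                axis=-1, mode="nearest")
    lo, hi = spec.analysis_window
    lo = max(lo, epochs.time[0])
    hi = min(hi, epochs.time[-1])
    i0, i1 = epochs.index_of(lo), epochs.index_of(hi)
    data = data[:, :, i0:i1 + 1:spec.step].copy()
    time = epochs.time[i0:i1 + 1:spec.step].copy()

    if spec.day_max_normalize:
        days = epochs.days
        for day in np.unique(days):
            sel = days == day
            m = np.max(np.abs(data[sel]))
            if m == 0:
                raise ValueError(f"day {day!r} contains only zeros; max-normalization undefined")
            data[sel] /= m
    if spec.channel_zscore:
        mean = data.mean(axis=(0, 2), keepdims=True)
        sd = data.std(axis=(0, 2), keepdims=True)
        zero = sd == 0
        if np.any(zero):
            logger.info("z-scoring: %d zero-variance channel(s) set to zero", int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
        data = (data - mean) / sd
        data[np.broadcast_to(zero, data.shape)] = 0.0
    return EpochSet(data=data, channel_names=list(epochs.channel_names),
                    time=time, trial_meta=epochs.trial_meta.copy())


# ---------------------------------------------------------------------------
# pooled covariance / precision


def _pooled_cov(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Trial-count-weighted pooling of the two per-condition covariances."""
    na, nb = xa.shape[0], xb.shape[0]
    ca = np.atleast_2d(np.cov(xa, rowvar=False))
    cb = np.atleast_2d(np.cov(xb, rowvar=False))
    return ((na - 1) * ca + (nb - 1) * cb) / (na + nb - 2)


def _shrink(cov: np.ndarray, xa: np.ndarray, xb: np.ndarray,
            policy: str | float, lam: float) -> np.ndarray:
    if policy == "none":
        return cov
    mu = float(np.trace(cov)) / cov.shape[0]
    if policy == "fixed":
        pass
    elif policy == "lw":
        centered = np.vstack([xa - xa.mean(0), xb - xb.mean(0)])
        lam = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
    elif isinstance(policy, (int, float)):
        lam = float(policy)
    else:
        raise ValueError(f"unknown shrinkage policy {policy!r}")
    return (1.0 - lam) * cov + lam * mu * np.eye(cov.shape[0])


def _pooled_precision_patterns(xa: np.ndarray, xb: np.ndarray,
                               shrinkage: str | float = "fixed",
                               shrinkage_lambda: float = 0.1) -> np.ndarray:
    cov = _pooled_cov(xa, xb)
    cov = _shrink(cov, xa, xb, shrinkage, shrinkage_lambda)
    if shrinkage == "none":
        rank = np.linalg.matrix_rank(cov)
        if rank < cov.shape[0]:
            logger.warning("pooled covariance rank-deficient (%d/%d); pseudo-inverse used",
                           rank, cov.shape[0])
    return np.linalg.pinv(cov, hermitian=True)


def pooled_precision(epochs_a: EpochSet, epochs_b: EpochSet, t: float,
                     shrinkage: str | float = "fixed",
                     shrinkage_lambda: float = 0.1) -> np.ndarray:
    """Pseudo-inverse of the pooled channel covariance at time ``t`` (ms)."""
    if epochs_a.n_trials < 2 or epochs_b.n_trials < 2:
        raise ValueError("need >= 2 trials per condition for a covariance")
    xa = epochs_a.data[:, :, epochs_a.index_of(t)]
    xb = epochs_b.data[:, :, epochs_b.index_of(t)]
    return _pooled_precision_patterns(xa, xb, shrinkage, shrinkage_lambda)


# ---------------------------------------------------------------------------
# cross-validated dissimilarity


def _one_side(xa: np.ndarray, xb: np.ndarray, prec: np.ndarray,
              cross_validate: bool) -> float:
    """D12 - D11 from condition a's perspective at one time point."""
    n = xa.shape[0]
    if cross_validate:
        loo_means = (xa.sum(axis=0, keepdims=True) - xa) / (n - 1)
    else:
        loo_means = np.broadcast_to(xa.mean(axis=0, keepdims=True), xa.shape)
    d1 = loo_means - xa
    d2 = xb.mean(axis=0, keepdims=True) - xa
    d11 = np.sqrt(np.maximum(np.einsum("ic,cd,id->i", d1, prec, d1), 0.0)).mean()
    d12 = np.sqrt(np.maximum(np.einsum("ic,cd,id->i", d2, prec, d2), 0.0)).mean()
    return float(d12 - d11)


def _dissim_matched(xa: np.ndarray, xb: np.ndarray, shrinkage, lam,
                    cross_validate: bool, symmetrize: bool) -> np.ndarray:
    """Dissimilarity time course for equal-sized trial sets (n, c, T)."""
    n_t = xa.shape[2]
    out = np.empty(n_t)
    for t in range(n_t):
        a, b = xa[:, :, t], xb[:, :, t]
        prec = _pooled_precision_patterns(a, b, shrinkage, lam)
        v = _one_side(a, b, prec, cross_validate)
        if symmetrize:
            v = 0.5 * (v + _one_side(b, a, prec, cross_validate))
        out[t] = v
    return out


def dissimilarity_arrays(
    xa: np.ndarray,
    xb: np.ndarray,
    n_subsample_iters: int = 10,
    seed: int = 0,
    shrinkage: str | float = "fixed",
    shrinkage_lambda: float = 0.1,
    cross_validate: bool = True,
    symmetrize: bool = True,
) -> np.ndarray:
    """Core D12 - D11 computation on raw (trials, channels, time) arrays.

    Unequal trial counts are handled by averaging over ``n_subsample_iters``
    seeded random subsamples of the larger set; with equal counts the result
    is computed once and is seed-independent.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.ndim != 3 or xb.ndim != 3:
        raise ValueError("inputs must be trials x channels x time")
    if xa.shape[1:] != xb.shape[1:]:
        raise ValueError("channel/time axes must match between conditions")
    if min(xa.shape[0], xb.shape[0]) < 3:
        raise ValueError("need >= 3 trials per condition (leave-one-out mean undefined)")
    na, nb = xa.shape[0], xb.shape[0]
    if na == nb:
        return _dissim_matched(xa, xb, shrinkage, shrinkage_lambda,
                               cross_validate, symmetrize)
    rng = np.random.default_rng(seed)
    n = min(na, nb)
    acc = np.zeros(xa.shape[2])
    for _ in range(n_subsample_iters):
        sa = xa[rng.choice(na, n, replace=False)] if na > n else xa
        sb = xb[rng.choice(nb, n, replace=False)] if nb > n else xb
        acc += _dissim_matched(sa, sb, shrinkage, shrinkage_lambda,
                               cross_validate, symmetrize)
    return acc / n_subsample_iters


def crossval_dissimilarity(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    n_subsample_iters: int = 10,
    seed: int = 0,
    shrinkage: str | float = "fixed",
    shrinkage_lambda: float = 0.1,
    cross_validate: bool = True,
    symmetrize: bool = True,
    condition_pair: tuple = ("cond1", "cond2"),
    slice_label: str = "",
) -> DissimilarityTrace:
    """Cross-validated Mahalanobis dissimilarity between two epoch sets.

    Both sets must already be preprocessed on the same axis and channels.
    """
    if epochs_a.data.shape[1] != epochs_b.data.shape[1] or \
            not np.array_equal(epochs_a.time, epochs_b.time):
        raise ValueError("epoch sets must share channels and time axis")
    value = dissimilarity_arrays(
        epochs_a.data, epochs_b.data,
        n_subsample_iters=n_subsample_iters, seed=seed,
        shrinkage=shrinkage, shrinkage_lambda=shrinkage_lambda,
        cross_validate=cross_validate, symmetrize=symmetrize,
    )
    return DissimilarityTrace(
        time=epochs_a.time.copy(), value=value,
        condition_pair=condition_pair, slice_label=slice_label,
        n_trials_used=(epochs_a.n_trials, epochs_b.n_trials),
        subsample_iterations=n_subsample_iters if epochs_a.n_trials != epochs_b.n_trials else 1,
        seed=seed,
    )


def feature_dissimilarity(
    features_a: Sequence[FeatureTrace],
    features_b: Sequence[FeatureTrace],
    seed: int = 0,
    n_subsample_iters: int = 10,
    shrinkage: str | float = "fixed",
    shrinkage_lambda: float = 0.1,
    condition_pair: tuple = ("cond1", "cond2"),
    slice_label: str = "",
) -> DissimilarityTrace:
    """D12 - D11 over the (horizontal, vertical) components of a feature."""
    features_a, features_b = list(features_a), list(features_b)
    if not features_a or not features_b:
        raise ValueError("both feature collections must be non-empty")
    kinds = {f.kind for f in features_a} | {f.kind for f in features_b}
    if len(kinds) != 1:
        raise ValueError(f"mixed feature kinds {sorted(kinds)}; use one kind per call")
    time = features_a[0].time
    for f in features_a + features_b:
        if not np.array_equal(f.time, time):
            raise ValueError("all feature traces must share one time axis")
    xa = np.stack([[f.h, f.v] for f in features_a])
    xb = np.stack([[f.h, f.v] for f in features_b])
    value = dissimilarity_arrays(
        xa, xb, n_subsample_iters=n_subsample_iters, seed=seed,
        shrinkage=shrinkage, shrinkage_lambda=shrinkage_lambda,
    )
    return DissimilarityTrace(
        time=time.copy(), value=value,
        condition_pair=condition_pair,
        slice_label=slice_label or kinds.pop(),
        n_trials_used=(len(features_a), len(features_b)),
        subsample_iterations=n_subsample_iters if len(features_a) != len(features_b) else 1,
        seed=seed,
    )


def select_channels(epochs: EpochSet, group: str | Sequence[str]) -> EpochSet:
    """Channel-subset copy by named group or explicit name list.

    Built-in groups: ``default-47`` (full montage minus noise-prone
    channels), ``frontal-central`` (13 channels), ``central-parietal``
    (14 channels), ``all-64``.
    """
    if isinstance(group, str):
        if group not in CHANNEL_GROUPS:
            raise KeyError(f"unknown channel group {group!r}; "
                           f"available: {sorted(CHANNEL_GROUPS)}")
        names = CHANNEL_GROUPS[group]
    else:
        names = list(group)
    missing = [n for n in names if n not in epochs.channel_names]
    if missing:
        raise KeyError(f"channels not present in epochs: {missing}")
    idx = [epochs.channel_names.index(n) for n in names]
    return EpochSet(
        data=epochs.data[:, idx, :].copy(),
        channel_names=list(names),
        time=epochs.time.copy(),
        trial_meta=epochs.trial_meta.copy(),
    )
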