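"""Nonparametric cluster-based permutation tests and scalar t-tests.

Time-resolved group effects are tested against zero with a one-sample t at
every sample, clustering contiguous supra-threshold samples of a common
sign, and comparing each cluster's summed t (its mass) with the permutation
distribution of the maximum |mass| obtained by randomly sign-flipping whole
participant traces. Flipping at the participant level is the exact
exchangeability scheme for a test against zero and controls the
family-wise error rate across time two-sidedly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list
    threshold_p: float
    n_permutations: int
    seed: int
    time: np.ndarray
    t_values: np.ndarray
    null_max_abs_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p < 0.05]


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t across rows (participants); 0/0 -> 0."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _clusters_from_t(t: np.ndarray, t_crit: float) -> list[tuple[int, int, int, float]]:
    """(start_idx, end_idx, sign, mass) for runs of same-sign |t| > t_crit."""
    above = np.abs(t) > t_crit
    if not above.any():
        return []
    sign = np.sign(t).astype(int)
    out = []
    start = None
    for i in range(t.size):
        if above[i] and (start is None or sign[i] != cur_sign):
            if start is not None:
                out.append((start, i - 1, cur_sign, float(t[start:i].sum())))
            start, cur_sign = i, sign[i]
        elif not above[i] and start is not None:
            out.append((start, i - 1, cur_sign, float(t[start:i].sum())))
            start = None
    if start is not None:
        out.append((start, t.size - 1, cur_sign, float(t[start:].sum())))
    return out


def _max_abs_mass(t: np.ndarray, t_crit: float) -> float:
    cl = _clusters_from_t(t, t_crit)
    return max((abs(m) for *_, m in cl), default=0.0)


def cluster_test(
    traces: np.ndarray,
    time: np.ndarray | None = None,
    threshold_p: float = 0.05,
    n_perm: int = 50_000,
    seed: int = 0,
    paired_with: np.ndarray | None = None,
) -> ClusterResult:
    """Two-sided cluster-based sign-flip permutation test against zero.

    ``traces`` is participants x time; if ``paired_with`` is given the test
    is applied to the paired difference. ``threshold_p`` is the two-sided
    cluster-defining p for the pointwise t; corrected p-values use the
    (count + 1) / (n_perm + 1) convention so they are never exactly zero.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2:
        raise ValueError("traces must be participants x time")
    if paired_with is not None:
        other = np.asarray(paired_with, dtype=float)
        if other.shape != x.shape:
            raise ValueError("paired_with must match traces' shape")
        x = x - other
    n_part, n_time = x.shape
    if n_part < 2:
        raise ValueError("need >= 2 participants")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse")
    if time is None:
        time = np.arange(n_time, dtype=float)
    time = np.asarray(time, dtype=float)

    t_crit = float(sps.t.ppf(1.0 - threshold_p / 2.0, df=n_part - 1))
    t_obs = _t_one_sample(x)
    observed = _clusters_from_t(t_obs, t_crit)

    # Sign-flip null: column sums of squares are flip-invariant, so the
    # permuted t-series follows from the flipped means alone.
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_part))
    col_ss = np.sum(x ** 2, axis=0)
    means = signs @ x / n_part
    var = (col_ss - n_part * means ** 2) / (n_part - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(var > 0, means / np.sqrt(var / n_part), 0.0)
    null_max = np.fromiter(
        (_max_abs_mass(t_perm[k], t_crit) for k in range(n_perm)),
        dtype=float, count=n_perm)

    clusters = []
    for start, end, sign, mass in observed:
        p = (1.0 + float(np.sum(null_max >= abs(mass)))) / (n_perm + 1.0)
        clusters.append(Cluster(
            start_ms=float(time[start]), end_ms=float(time[end]),
            sign=int(sign), mass=mass, p=p,
        ))
    return ClusterResult(
        clusters=clusters, threshold_p=threshold_p, n_permutations=n_perm,
        seed=seed, time=time, t_values=t_obs, null_max_abs_mass=null_max,
    )


def scalar_tests(
    a: np.ndarray,
    b: np.ndarray | None = None,
    kind: str = "one_sample",
    popmean: float = 0.0,
) -> tuple[float, float]:
    """Standard t statistics with two-sided p for scalar summaries."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need >= 2 values per group")
    if kind == "one_sample":
        if np.std(a, ddof=1) == 0 and not np.isclose(a.mean(), popmean):
            raise ValueError("zero variance: t statistic undefined")
    elif kind in ("two_sample", "paired"):
        if b is None:
            raise ValueError(f"{kind} test needs a second group")
        b = np.asarray(b, dtype=float)
        if b.size < 2:
            raise ValueError("need >= 2 values per group")
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0 \
                and not np.allclose(a.mean(), b.mean()):
            raise ValueError("zero variance: t statistic undefined")
    else:
        raise ValueError("kind must be one_sample, two_sample, or paired")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant groups -> t=0, p=1
        if kind == "one_sample":
            res = sps.ttest_1samp(a, popmean)
        elif kind == "two_sample":
            res = sps.ttest_ind(a, b)
        else:
            res = sps.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # identical constant groups: no effect, no evidence
        t, p = 0.0, 1.0
    return t, p
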