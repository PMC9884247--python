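from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pursuitmvpa import SimulationConfig, generate_eye_traces


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small but fully featured simulation: 3 directions x 2 contrasts."""
    return SimulationConfig(n_trials_per_cell=4, n_channels=6, seed=7)


@pytest.fixture(scope="session")
def tiny_traces(tiny_config):
    return generate_eye_traces(tiny_config)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(
        n_trials_per_cell=3, n_channels=5, noise_sd=0.0,
        latency_jitter_sd=0.0, saccade_rate=0.0, seed=11,
    )


def oracle_crossval_dissimilarity(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Literal loop transcription of the leave-one-out Mahalanobis scheme.

    Independent oracle: per time point, pool the two condition covariances
    (trial-count weighted), pseudo-invert, and average the per-trial
    distances to the leave-one-out own mean (D11) and the other-condition
    mean (D12); both condition-role assignments are averaged. Equal trial
    counts, no shrinkage.
    """
    n, _, n_t = xa.shape
    assert xb.shape[0] == n
    out = np.zeros(n_t)
    for t in range(n_t):
        a, b = xa[:, :, t], xb[:, :, t]
        ca = np.atleast_2d(np.cov(a, rowvar=False))
        cb = np.atleast_2d(np.cov(b, rowvar=False))
        pooled = ((n - 1) * ca + (n - 1) * cb) / (2 * n - 2)
        prec = np.linalg.pinv(pooled)
        vals = []
        for x, y in ((a, b), (b, a)):
            d11 = d12 = 0.0
            for i in range(n):
                td = x[i]
                td1 = (x.sum(axis=0) - td) / (n - 1)
                td2 = y.mean(axis=0)
                d11 += np.sqrt(max((td1 - td) @ prec @ (td1 - td), 0.0))
                d12 += np.sqrt(max((td2 - td) @ prec @ (td2 - td), 0.0))
            vals.append((d12 - d11) / n)
        out[t] = 0.5 * (vals[0] + vals[1])
    return out
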