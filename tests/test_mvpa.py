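"""Preprocessing, pooled precision, and cross-validated dissimilarity."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pursuitmvpa import (
    EpochSet,
    PreprocessSpec,
    SimulationConfig,
    crossval_dissimilarity,
    dissimilarity_arrays,
    feature_dissimilarity,
    generate_epochs,
    generate_eye_traces,
    pooled_precision,
    preprocess_epochs,
    select_channels,
)
from pursuitmvpa.features import feature_for_trial
from pursuitmvpa.montage import ACTICAP_64

from .conftest import oracle_crossval_dissimilarity


def make_epochs(data, days=None, channel_names=None, t0=0.0):
    n_tr, n_ch, n_t = data.shape
    meta = pd.DataFrame({
        "trial_id": [f"t{i}" for i in range(n_tr)],
        "day": days if days is not None else ["day1"] * n_tr,
    })
    return EpochSet(
        data=data,
        channel_names=channel_names or [f"ch{i}" for i in range(n_ch)],
        time=np.arange(t0, t0 + n_t),
        trial_meta=meta,
    )


class TestPreprocess:
    def test_impulse_smoothed_to_rectangle(self):
        data = np.zeros((1, 1, 101))
        data[0, 0, 50] = 1.0
        ep = make_epochs(data)
        out = preprocess_epochs(ep, PreprocessSpec(day_max_normalize=False,
                                                   channel_zscore=False,
                                                   analysis_window=(0, 100)))
        np.testing.assert_allclose(out.data[0, 0, 40:61], 1 / 21, atol=1e-12)
        assert out.data[0, 0, 39] == 0.0 and out.data[0, 0, 61] == 0.0

    def test_constant_channel_zeroed_by_zscore(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 3, 50))
        data[:, 1, :] = 2.5  # constant channel
        out = preprocess_epochs(make_epochs(data),
                                PreprocessSpec(smooth_halfwidth=0, analysis_window=(0, 49)))
        np.testing.assert_array_equal(out.data[:, 1, :], 0.0)

    def test_identical_days_identical_outputs(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(3, 2, 40))
        data = np.concatenate([block, block])
        days = ["day1"] * 3 + ["day2"] * 3
        out = preprocess_epochs(make_epochs(data, days=days),
                                PreprocessSpec(analysis_window=(0, 39)))
        np.testing.assert_allclose(out.data[:3], out.data[3:], atol=1e-12)

    def test_all_zero_day_raises(self):
        data = np.zeros((2, 2, 30))
        with pytest.raises(ValueError, match="max-normalization"):
            preprocess_epochs(make_epochs(data), PreprocessSpec(analysis_window=(0, 29)))

    def test_zscore_makes_channels_unit_variance(self):
        rng = np.random.default_rng(2)
        data = 5 + 3 * rng.normal(size=(6, 4, 80))
        out = preprocess_epochs(make_epochs(data),
                                PreprocessSpec(smooth_halfwidth=0, analysis_window=(0, 79)))
        sd = out.data.std(axis=(0, 2))
        np.testing.assert_allclose(sd, 1.0, atol=1e-9)


class TestPooledPrecision:
    def test_scalar_case_is_inverse_pooled_variance(self):
        rng = np.random.default_rng(3)
        xa = rng.normal(size=(10, 1, 5))
        xb = rng.normal(size=(8, 1, 5))
        ea, eb = make_epochs(xa), make_epochs(xb)
        prec = pooled_precision(ea, eb, t=2.0, shrinkage="none")
        va = np.var(xa[:, 0, 2], ddof=1)
        vb = np.var(xb[:, 0, 2], ddof=1)
        pooled = (9 * va + 7 * vb) / 16
        assert prec[0, 0] == pytest.approx(1.0 / pooled)

    def test_full_shrinkage_gives_scaled_identity(self):
        rng = np.random.default_rng(4)
        ea = make_epochs(rng.normal(size=(10, 3, 5)))
        eb = make_epochs(rng.normal(size=(10, 3, 5)))
        prec = pooled_precision(ea, eb, t=0.0, shrinkage=1.0)
        off = prec - np.diag(np.diag(prec))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(prec), prec[0, 0])

    def test_iid_unit_variance_precision_near_identity(self):
        rng = np.random.default_rng(5)
        ea = make_epochs(rng.normal(size=(2000, 3, 2)))
        eb = make_epochs(rng.normal(size=(2000, 3, 2)))
        prec = pooled_precision(ea, eb, t=0.0, shrinkage="none")
        np.testing.assert_allclose(prec, np.eye(3), atol=0.1)


class TestCrossvalDissimilarity:
    def test_matches_literal_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            c = int(rng.integers(1, 5))
            n_t = int(rng.integers(2, 6))
            xa = rng.normal(size=(n, c, n_t))
            xb = rng.normal(size=(n, c, n_t)) + rng.normal() * 0.5
            got = dissimilarity_arrays(xa, xb, shrinkage="none")
            want = oracle_crossval_dissimilarity(xa, xb)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_identity_precision_reduces_to_euclidean(self):
        """With unit precision forced, distances are plain Euclidean."""
        rng = np.random.default_rng(7)
        xa = rng.normal(size=(8, 3, 1))
        xb = rng.normal(size=(8, 3, 1)) + 1.0
        from pursuitmvpa.mvpa import _one_side
        prec = np.eye(3)
        a, b = xa[:, :, 0], xb[:, :, 0]
        got = _one_side(a, b, prec, cross_validate=True)
        n = a.shape[0]
        d11 = np.mean([np.linalg.norm((a.sum(0) - a[i]) / (n - 1) - a[i]) for i in range(n)])
        d12 = np.mean([np.linalg.norm(b.mean(0) - a[i]) for i in range(n)])
        assert got == pytest.approx(d12 - d11, abs=1e-12)

    def test_exchangeable_null_near_zero(self):
        rng = np.random.default_rng(8)
        xa = rng.normal(size=(100, 4, 30))
        xb = rng.normal(size=(100, 4, 30))
        v = dissimilarity_arrays(xa, xb)
        se = v.std(ddof=1) / np.sqrt(v.size)  # conservative MC scale
        assert abs(v.mean()) < 2 * max(se, 0.01)

    def test_naive_variant_positively_biased_under_null(self):
        rng = np.random.default_rng(9)
        cv_means, naive_means = [], []
        for _ in range(30):
            xa = rng.normal(size=(12, 3, 8))
            xb = rng.normal(size=(12, 3, 8))
            cv_means.append(dissimilarity_arrays(xa, xb).mean())
            naive_means.append(
                dissimilarity_arrays(xa, xb, cross_validate=False).mean())
        assert np.mean(naive_means) > np.mean(cv_means) + 0.05
        assert abs(np.mean(cv_means)) < 0.05

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(10)
        xa = rng.normal(size=(10, 5, 6))
        xb = rng.normal(size=(10, 5, 6)) + 0.3
        perm = rng.permutation(5)
        a = dissimilarity_arrays(xa, xb, shrinkage="none")
        b = dissimilarity_arrays(xa[:, perm], xb[:, perm], shrinkage="none")
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_invariance_under_common_invertible_map(self):
        rng = np.random.default_rng(11)
        xa = rng.normal(size=(20, 4, 5))
        xb = rng.normal(size=(20, 4, 5)) + 0.4
        m = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        ya = np.einsum("dc,ncT->ndT", m, xa)
        yb = np.einsum("dc,ncT->ndT", m, xb)
        a = dissimilarity_arrays(xa, xb, shrinkage="none")
        b = dissimilarity_arrays(ya, yb, shrinkage="none")
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_equal_counts_seed_independent(self):
        rng = np.random.default_rng(12)
        xa = rng.normal(size=(8, 3, 4))
        xb = rng.normal(size=(8, 3, 4))
        np.testing.assert_array_equal(
            dissimilarity_arrays(xa, xb, seed=1),
            dissimilarity_arrays(xa, xb, seed=99))

    def test_unequal_counts_subsampled_and_reproducible(self):
        rng = np.random.default_rng(13)
        xa = rng.normal(size=(15, 3, 4))
        xb = rng.normal(size=(8, 3, 4))
        a = dissimilarity_arrays(xa, xb, seed=5, n_subsample_iters=4)
        b = dissimilarity_arrays(xa, xb, seed=5, n_subsample_iters=4)
        c = dissimilarity_arrays(xa, xb, seed=6, n_subsample_iters=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="leave-one-out"):
            dissimilarity_arrays(rng.normal(size=(2, 3, 4)),
                                 rng.normal(size=(8, 3, 4)))

    def test_synthetic_directions_separate_and_noise_monotone(self):
        """0 vs -60 deg epochs: positive dissimilarity, larger at low noise."""
        results = {}
        for noise in (0.8, 0.2):
            cfg = SimulationConfig(n_trials_per_cell=15, n_channels=8,
                                   noise_sd=noise, seed=20)
            traces = [t for t in generate_eye_traces(cfg)
                      if t.block == "valid" and np.isclose(t.contrast, 1.0)]
            ep = preprocess_epochs(generate_epochs(traces, cfg),
                                   PreprocessSpec(analysis_window=(-100, 500)))
            up = ep.select_trials(target_direction=0.0)
            lo = ep.select_trials(target_direction=-60.0)
            tr = crossval_dissimilarity(up, lo)
            window = (tr.time >= 100) & (tr.time <= 330)
            results[noise] = tr.value[window].mean()
        assert results[0.2] > results[0.8] > 0


class TestFeatureDissimilarity:
    def test_identical_groups_near_zero(self, tiny_traces, tiny_config):
        feats = [feature_for_trial(t, "eye_velocity") for t in tiny_traces[:8]]
        tr = feature_dissimilarity(feats[:4], feats[4:])
        assert np.isfinite(tr.value).all()

    def test_direction_ramps_positive_after_latency(self):
        cfg = SimulationConfig(n_trials_per_cell=10, n_channels=4,
                               noise_sd=0.0, latency_jitter_sd=3.0, seed=21)
        traces = [t for t in generate_eye_traces(cfg)
                  if t.block == "valid" and np.isclose(t.contrast, 1.0)]
        up = [feature_for_trial(t, "eye_velocity") for t in traces
              if t.target_direction == 0.0]
        lo = [feature_for_trial(t, "eye_velocity") for t in traces
              if t.target_direction == -60.0]
        tr = feature_dissimilarity(up, lo)
        before = tr.value[(tr.time >= -100) & (tr.time <= 50)]
        after = tr.value[(tr.time >= 200) & (tr.time <= 400)]
        assert after.mean() > 10 * max(abs(before.mean()), 0.1)

    def test_mixed_kinds_rejected(self, tiny_traces):
        a = [feature_for_trial(t, "eye_velocity") for t in tiny_traces[:4]]
        b = [feature_for_trial(t, "eye_position") for t in tiny_traces[4:8]]
        with pytest.raises(ValueError, match="kind"):
            feature_dissimilarity(a, b)


class TestSelectChannels:
    def _epochs64(self):
        rng = np.random.default_rng(15)
        return make_epochs(rng.normal(size=(4, 64, 5)), channel_names=list(ACTICAP_64))

    def test_all_group_is_identity(self):
        ep = self._epochs64()
        out = select_channels(ep, "all-64")
        np.testing.assert_array_equal(out.data, ep.data)
        assert out.channel_names == ep.channel_names

    def test_group_sizes(self):
        ep = self._epochs64()
        assert select_channels(ep, "default-47").data.shape[1] == 47
        assert select_channels(ep, "frontal-central").data.shape[1] == 13
        assert select_channels(ep, "central-parietal").data.shape[1] == 14

    def test_unknown_channel_listed_in_error(self):
        ep = self._epochs64()
        with pytest.raises(KeyError, match="Xz"):
            select_channels(ep, ["Cz", "Xz"])

    def test_unknown_group_rejected(self):
        with pytest.raises(KeyError, match="unknown channel group"):
            select_channels(self._epochs64(), "occipital")
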