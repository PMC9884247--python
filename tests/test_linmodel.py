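"""Design assembly, profiled grid fitting, and residual analysis."""

from __future__ import annotations

import numpy as np
import pytest

from pursuitmvpa import build_design, fit, residual_analysis

TIME = np.arange(-100.0, 501.0)
CONDS = [("valid", 1.0), ("invalid", 1.0), ("valid", 0.12), ("invalid", 0.12)]
SCALES = [1.0, 0.8, 0.6, 0.9]


def sigmoid(center, width):
    return 1.0 / (1.0 + np.exp(-(TIME - center) / width))


def shift(sig, s):
    idx = np.clip(np.arange(sig.size) + int(s), 0, sig.size - 1)
    return sig[idx]


def normalized(per_cond):
    allv = np.concatenate(list(per_cond.values()))
    lo, hi = allv.min(), allv.max()
    return {c: (v - lo) / (hi - lo) for c, v in per_cond.items()}


def make_problem(w_s=1.2, w_m=0.5, t_s=-35, t_m=27, noise_sd=0.0, seed=0,
                 s_center=150.0, m_center=220.0):
    """Neural traces generated from the shifted normalized regressors."""
    regs = {
        "irve": {c: sigmoid(s_center, 30.0) * sc for c, sc in zip(CONDS, SCALES)},
        "eye_velocity": {c: sigmoid(m_center, 20.0) * sc for c, sc in zip(CONDS, SCALES)},
    }
    ns = normalized(regs["irve"])
    nm = normalized(regs["eye_velocity"])
    rng = np.random.default_rng(seed)
    neural = {}
    for c in CONDS:
        clean = w_s * shift(ns[c], t_s) + w_m * shift(nm[c], t_m)
        neural[c] = clean + noise_sd * rng.normal(size=TIME.size)
    return neural, regs


class TestBuildDesign:
    def test_window_row_count(self):
        neural, regs = make_problem()
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        assert d.y.size == 301 * 4
        assert d.n_per_cond == 301

    def test_maxmin_scale_invariance(self):
        neural, regs = make_problem()
        d1 = build_design(neural, regs, window=(30, 330), time=TIME)
        scaled = {k: {c: 10.0 * v for c, v in per.items()} for k, per in regs.items()}
        d2 = build_design(neural, scaled, window=(30, 330), time=TIME)
        for kind in regs:
            for c in CONDS:
                np.testing.assert_allclose(d1.regressors[kind][c],
                                           d2.regressors[kind][c], atol=1e-12)

    def test_constant_regressor_zeroed(self):
        neural, regs = make_problem()
        regs["eye_velocity"] = {c: np.full(TIME.size, 7.0) for c in CONDS}
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        for c in CONDS:
            np.testing.assert_array_equal(d.regressors["eye_velocity"][c], 0.0)

    def test_window_outside_axis_rejected(self):
        neural, regs = make_problem()
        with pytest.raises(ValueError):
            build_design(neural, regs, window=(30, 900), time=TIME)


class TestFit:
    def test_noiseless_exact_recovery(self):
        neural, regs = make_problem()
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f = fit(d, shift_bounds=(-100, 100))
        assert (f.t_s, f.t_m) == (-35.0, 27.0)
        assert f.weights["irve"] == pytest.approx(1.2, abs=1e-8)
        assert f.weights["eye_velocity"] == pytest.approx(0.5, abs=1e-8)
        assert f.r_squared == pytest.approx(1.0, abs=1e-10)
        assert f.rss == pytest.approx(0.0, abs=1e-12)

    def test_predictions_plus_residuals_reconstruct_observed(self):
        neural, regs = make_problem(noise_sd=0.05)
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f = fit(d, shift_bounds=(-60, 60))
        for c in CONDS:
            np.testing.assert_allclose(f.predictions[c] + f.residuals[c],
                                       f.observed[c], atol=1e-12)

    def test_full_model_nests_reduced(self):
        neural, regs = make_problem(noise_sd=0.05)
        regs["retinal_velocity_error"] = {c: sigmoid(120.0, 40.0) * sc
                                          for c, sc in zip(CONDS, SCALES)}
        regs["eye_position"] = {c: sigmoid(260.0, 35.0) * sc
                                for c, sc in zip(CONDS, SCALES)}
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f_red = fit(d, variant="reduced", shift_bounds=(-60, 60))
        f_full = fit(d, variant="full", shift_bounds=(-60, 60))
        assert f_full.r_squared >= f_red.r_squared - 1e-12
        assert set(f_full.weights) == {"irve", "retinal_velocity_error",
                                       "eye_velocity", "eye_position"}
        assert set(f_red.weights) == {"irve", "eye_velocity"}

    def test_grid_is_seed_invariant(self):
        neural, regs = make_problem(noise_sd=0.1, seed=3)
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f1 = fit(d, shift_bounds=(-60, 60), seed=1)
        f2 = fit(d, shift_bounds=(-60, 60), seed=999)
        assert (f1.t_s, f1.t_m, f1.rss) == (f2.t_s, f2.t_m, f2.rss)

    @pytest.mark.parametrize("seed", range(6))
    def test_multistart_matches_grid(self, seed):
        neural, regs = make_problem(noise_sd=0.08, seed=seed)
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        g = fit(d, shift_bounds=(-100, 100), search="grid")
        m = fit(d, shift_bounds=(-100, 100), search="multistart", seed=seed,
                n_starts=50)
        assert m.rss <= g.rss * (1 + 1e-6) + 1e-12

    def test_bounds_exceeding_coverage_rejected(self):
        neural, regs = make_problem()
        with pytest.raises(ValueError, match="coverage"):
            d = build_design(neural, regs, window=(30, 330), time=TIME)
            fit(d, shift_bounds=(-200, 200))

    def test_recovery_degrades_gracefully_with_noise(self):
        """Bias shrinks toward zero as noise does; ordering is monotone."""
        errs = {}
        for noise in (0.0, 0.05, 0.4):
            ts_err = []
            for seed in range(8):
                neural, regs = make_problem(noise_sd=noise, seed=seed)
                d = build_design(neural, regs, window=(30, 330), time=TIME)
                f = fit(d, shift_bounds=(-80, 80))
                ts_err.append(abs(f.t_s - (-35.0)))
            errs[noise] = np.median(ts_err)
        assert errs[0.0] == 0.0
        assert errs[0.0] <= errs[0.05] <= errs[0.4] + 1e-9

    def test_intercept_makes_residuals_zero_mean(self):
        neural, regs = make_problem(noise_sd=0.05, seed=4)
        neural = {c: v + 0.3 for c, v in neural.items()}
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f = fit(d, shift_bounds=(-60, 60), intercept=True)
        all_res = np.concatenate([f.residuals[c] for c in CONDS])
        assert all_res.mean() == pytest.approx(0.0, abs=1e-10)


class TestResiduals:
    def test_noiseless_residuals_zero(self):
        neural, regs = make_problem()
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f = fit(d, shift_bounds=(-60, 60))
        residuals, diffs = residual_analysis(f)
        for c in CONDS:
            np.testing.assert_allclose(residuals[c], 0.0, atol=1e-10)
        for contrast in (1.0, 0.12):
            np.testing.assert_allclose(diffs[contrast], 0.0, atol=1e-10)

    def test_injected_validity_effect_recovered(self):
        """An extra early bump in the low-contrast valid condition survives
        model subtraction with the right sign and window."""
        neural, regs = make_problem(noise_sd=0.01, seed=5)
        bump = 0.4 * np.exp(-0.5 * ((TIME - 110.0) / 10.0) ** 2)
        neural[("valid", 0.12)] = neural[("valid", 0.12)] + bump
        d = build_design(neural, regs, window=(30, 330), time=TIME)
        f = fit(d, shift_bounds=(-60, 60))
        _, diffs = residual_analysis(f)
        fit_time = np.arange(30.0, 331.0)
        inside = (fit_time >= 90) & (fit_time <= 130)
        outside = ~inside
        diff = diffs[0.12]
        assert diff[inside].mean() > 0.1
        assert diff[inside].mean() > 3 * abs(diff[outside].mean())
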