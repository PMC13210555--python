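import numpy as np
import pytest

from depotkit.dissolution import DissolutionProfile
from depotkit.ivivc import (
    IVIVC_MODELS,
    IVIVCPairs,
    fit_ivivc,
    pair_profiles,
    predict_absorbed,
    rank_ivivc,
)


def _pairs_from(model_fn, x=None):
    x = np.linspace(0.02, 0.95, 18) if x is None else x
    return IVIVCPairs(times=np.arange(len(x), dtype=float), f_dissolved=x, f_absorbed=model_fn(x))


class TestPairing:
    def test_identical_series_lie_on_identity_line(self):
        t = np.linspace(3.5, 100.0, 20)
        frac = np.linspace(0.01, 0.6, 20)
        diss = DissolutionProfile(times=t, cumulative_mass=frac * 100.0, loaded_mass=100.0)
        pairs = pair_profiles(diss, (t, frac), t)
        assert np.allclose(pairs.f_dissolved, pairs.f_absorbed)

    def test_constant_absorption_pairs_flat(self):
        t = np.linspace(3.5, 100.0, 10)
        diss = DissolutionProfile(
            times=t, cumulative_mass=np.linspace(1, 50, 10), loaded_mass=100.0
        )
        pairs = pair_profiles(diss, (t, np.full_like(t, 0.5)), t)
        assert np.allclose(pairs.f_absorbed, 0.5)

    def test_schedule_outside_span_rejected(self):
        t = np.linspace(3.5, 100.0, 10)
        diss = DissolutionProfile(
            times=t, cumulative_mass=np.linspace(1, 50, 10), loaded_mass=100.0
        )
        with pytest.raises(ValueError, match="schedule"):
            pair_profiles(diss, (t, np.linspace(0, 0.5, 10)), [50.0, 150.0])

    def test_lagged_weibull_pairing_matches_direct_evaluation(self):
        from depotkit.dissolution import weibull_cdf

        t = np.linspace(3.5, 182.0, 52)
        f_diss = weibull_cdf(t, 0.9, 50.0, 1.1)
        f_abs = weibull_cdf(t, 0.8, 80.0, 1.3)  # slower, lagged in time
        diss = DissolutionProfile(times=t, cumulative_mass=f_diss * 1e5, loaded_mass=1e5)
        pairs = pair_profiles(diss, (t, f_abs), t)
        assert np.allclose(pairs.f_dissolved, f_diss, atol=1e-12)
        assert np.allclose(pairs.f_absorbed, f_abs, atol=1e-12)


class TestFitIvivc:
    def test_exp_rise_3p_noise_free_recovery(self):
        truth = lambda x: 0.0 + 1.0 * (1.0 - np.exp(-3.0 * x))
        fit = fit_ivivc(_pairs_from(truth), "exp_rise_3p", seed=0)
        assert fit.parameters["y0"] == pytest.approx(0.0, abs=1e-6)
        assert fit.parameters["a"] == pytest.approx(1.0, rel=1e-6)
        assert fit.parameters["b"] == pytest.approx(3.0, rel=1e-6)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_sigmoid_4p_midpoint_identity(self):
        truth = lambda x: 0.05 + 0.8 / (1.0 + np.exp(-(x - 0.4) / 0.1))
        fit = fit_ivivc(_pairs_from(truth), "sigmoid_4p", seed=0)
        p = fit.parameters
        assert fit.predict(p["x0"]) == pytest.approx(p["y0"] + p["a"] / 2.0, rel=1e-9)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = IVIVCPairs(times=np.arange(4.0), f_dissolved=x, f_absorbed=x)
        with pytest.raises(ValueError, match="points"):
            fit_ivivc(pairs, "sigmoid_4p")

    def test_fit_invariant_to_point_order(self):
        truth = lambda x: 0.1 + 0.7 * x
        x = np.linspace(0.05, 0.9, 12)
        pairs = _pairs_from(truth, x)
        perm = np.random.default_rng(0).permutation(12)
        shuffled = IVIVCPairs(
            times=pairs.times[perm], f_dissolved=x[perm], f_absorbed=truth(x)[perm]
        )
        f1 = fit_ivivc(pairs, "linear_2p")
        f2 = fit_ivivc(shuffled, "linear_2p")
        assert f1.parameters["a"] == pytest.approx(f2.parameters["a"], rel=1e-9)

    def test_adjusted_r2_not_above_r2(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.05, 0.9, 15)
        y = 0.1 + 0.6 * x + rng.normal(0, 0.02, 15)
        pairs = IVIVCPairs(times=np.arange(15.0), f_dissolved=x, f_absorbed=np.clip(y, 0, 1))
        fit = fit_ivivc(pairs, "exp_rise_3p", seed=0)
        assert fit.r2_adj <= fit.r2


class TestRanking:
    def test_sigmoid_data_prefers_sigmoid_over_linear(self):
        truth = lambda x: 0.02 + 0.8 / (1.0 + np.exp(-(x - 0.45) / 0.08))
        pairs = _pairs_from(truth)
        fits = [fit_ivivc(pairs, m, seed=0) for m in ("linear_2p", "sigmoid_4p")]
        assert rank_ivivc(fits)[0].model == "sigmoid_4p"

    def test_linear_data_prefers_linear(self):
        truth = lambda x: 0.1 + 0.7 * x
        pairs = _pairs_from(truth)
        fits = [fit_ivivc(pairs, m, seed=0) for m in ("linear_2p", "sigmoid_4p", "exp_rise_3p")]
        assert rank_ivivc(fits)[0].model == "linear_2p"

    def test_noise_free_generated_data_wins_for_each_model(self):
        generators = {
            "linear_2p": lambda x: 0.05 + 0.8 * x,
            "exp_rise_3p": lambda x: 0.02 + 0.9 * (1 - np.exp(-2.5 * x)),
            "sigmoid_4p": lambda x: 0.02 + 0.85 / (1 + np.exp(-(x - 0.5) / 0.09)),
            "power_2p": lambda x: 0.9 * x**1.7,
        }
        for model, gen in generators.items():
            pairs = _pairs_from(gen)
            fits = [fit_ivivc(pairs, m, seed=0) for m in IVIVC_MODELS]
            winner = rank_ivivc(fits)[0]
            assert winner.ssr < 1e-10
            assert winner.model == model, f"{model} data won by {winner.model}"

    def test_single_candidate_identity(self):
        pairs = _pairs_from(lambda x: 0.1 + 0.7 * x)
        fit = fit_ivivc(pairs, "linear_2p")
        assert rank_ivivc([fit]) == [fit]


class TestPrediction:
    def test_prediction_equals_curve_at_observed_x(self):
        truth = lambda x: 0.05 + 0.8 * (1 - np.exp(-2.0 * x))
        pairs = _pairs_from(truth)
        fit = fit_ivivc(pairs, "exp_rise_3p", seed=0)
        out = predict_absorbed(fit, pairs.f_dissolved[5])
        assert out["prediction"][0] == pytest.approx(fit.predict(pairs.f_dissolved[5]))
        assert not out["extrapolated"][0]

    def test_bands_contain_fitted_curve(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.05, 0.9, 16)
        y = np.clip(0.1 + 0.6 * x + rng.normal(0, 0.03, 16), 0, 1)
        pairs = IVIVCPairs(times=np.arange(16.0), f_dissolved=x, f_absorbed=y)
        fit = fit_ivivc(pairs, "linear_2p")
        out = predict_absorbed(fit, np.linspace(0.1, 0.8, 9))
        assert np.all(out["lower"] <= out["prediction"])
        assert np.all(out["prediction"] <= out["upper"])

    def test_extrapolation_is_flagged(self):
        pairs = _pairs_from(lambda x: 0.1 + 0.7 * x)
        fit = fit_ivivc(pairs, "linear_2p")
        out = predict_absorbed(fit, [1.5])
        assert out["extrapolated"][0]
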