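import numpy as np
import pytest

from depotkit.deconvolution import (
    AbsorptionProfile,
    UIRFunction,
    build_uir,
    convolve,
    deconvolve,
    make_grid,
    remaining_percent,
    summarize_absorption,
)
from depotkit.iv_model import MacroModel


class TestBuildUIR:
    def test_coefficients_are_dose_normalized(self):
        model = MacroModel(coefficients=[1115.6, 102.0], exponents=[0.438, 0.170])
        dose = 2.25e6
        uir = build_uir(model, dose)
        assert uir.coefficients == pytest.approx([1115.6 / dose, 102.0 / dose])
        assert uir.exponents == [0.438, 0.170]

    def test_unit_dose_identity_and_linearity(self):
        model = MacroModel(coefficients=[10.0, 1.0], exponents=[0.5, 0.05])
        u1 = build_uir(model, 1.0)
        u2 = build_uir(model, 2.0)
        t = np.linspace(0, 48, 20)
        assert np.allclose(u1(t), model.predict(t))
        assert np.allclose(u2(t), model.predict(t) / 2.0)

    def test_nonpositive_dose_rejected(self):
        model = MacroModel(coefficients=[1.0], exponents=[0.1])
        with pytest.raises(ValueError):
            build_uir(model, 0.0)


@pytest.fixture()
def uir():
    return UIRFunction(coefficients=[5275.9 / 1.5e7, 6.3 / 1.5e7], exponents=[0.5, 0.1])


class TestConvolve:
    def test_zero_rate_gives_zero_concentration(self, uir):
        edges = make_grid(1000.0)
        c = convolve(uir, edges, np.zeros(len(edges) - 1), [10.0, 500.0, 999.0])
        assert np.allclose(c, 0.0)

    def test_constant_infusion_approaches_plateau(self, uir):
        k0 = 1000.0
        edges = np.array([0.0, 5e4])
        c = convolve(uir, edges, [k0], [4.9e4])
        assert c[0] == pytest.approx(k0 * uir.plateau_per_unit_rate, rel=1e-8)

    def test_superposition_and_linearity(self, uir):
        edges = make_grid(2000.0)
        rng = np.random.default_rng(0)
        r1 = rng.uniform(0, 100, len(edges) - 1)
        r2 = rng.uniform(0, 100, len(edges) - 1)
        t = np.linspace(0, 2000.0, 40)
        c12 = convolve(uir, edges, r1 + r2, t)
        assert np.allclose(c12, convolve(uir, edges, r1, t) + convolve(uir, edges, r2, t), atol=1e-12)
        doubled = UIRFunction(
            coefficients=[2 * c for c in uir.coefficients], exponents=uir.exponents
        )
        assert np.allclose(convolve(doubled, edges, r1, t), 2 * convolve(uir, edges, r1, t))

    def test_negative_rate_rejected(self, uir):
        with pytest.raises(ValueError, match="non-negative"):
            convolve(uir, [0.0, 10.0], [-1.0], [5.0])


class TestDeconvolve:
    def test_round_trip_recovers_step_input(self, uir):
        edges = make_grid(8928.0)  # day 1 node then 72-h segments to day 372
        rng = np.random.default_rng(3)
        r_true = rng.uniform(100.0, 2000.0, len(edges) - 1)
        t_obs = edges[1:]
        c = convolve(uir, edges, r_true, t_obs)
        prof = deconvolve(uir, t_obs, c, edges=edges, regularization=0.0)
        rel = np.abs(prof.rate[1:-1] - r_true[1:-1]) / r_true[1:-1]
        assert rel.max() < 1e-2

    def test_constant_rate_recovered_flat(self, uir):
        edges = make_grid(8928.0)
        k0 = 500.0
        t_obs = edges[1:]
        c = convolve(uir, edges, np.full(len(edges) - 1, k0), t_obs)
        prof = deconvolve(uir, t_obs, c, edges=edges, regularization=0.0)
        assert np.abs(prof.rate / k0 - 1.0).max() < 1e-2

    def test_cumulative_is_exact_integral_of_step_function(self, uir):
        edges = make_grid(2000.0)
        rate = np.linspace(10, 100, len(edges) - 1)
        prof = AbsorptionProfile(edges=edges, rate=rate)
        manual = np.cumsum(rate * np.diff(edges))
        assert np.allclose(prof.cumulative, manual)
        # interpolated cumulative matches mid-segment hand integration
        mid = (edges[3] + edges[4]) / 2.0
        expected = manual[2] + rate[3] * (mid - edges[3])
        assert prof.cumulative_at(mid) == pytest.approx(expected)

    def test_under_determined_without_regularization_raises(self, uir):
        edges = make_grid(8928.0)
        t_obs = edges[1:][::4]
        c = convolve(uir, edges, np.full(len(edges) - 1, 500.0), t_obs)
        with pytest.raises(ValueError, match="under-determined"):
            deconvolve(uir, t_obs, c, edges=edges, regularization=0.0)

    def test_gcv_regularized_solution_tracks_truth(self, uir):
        edges = make_grid(8928.0)
        k0 = 500.0
        t_obs = np.array([1.0, 7.0, 14.0] + list(range(28, 365, 14)), dtype=float) * 24.0
        c = convolve(uir, edges, np.full(len(edges) - 1, k0), t_obs)
        prof = deconvolve(uir, t_obs, c, edges=edges, regularization="gcv")
        interior = slice(2, -2)
        assert np.median(np.abs(prof.rate[interior] / k0 - 1.0)) < 0.05

    def test_input_shifted_by_whole_node_recovers_shifted_rates(self, uir):
        # time-invariance: delaying the input by one grid node shifts the
        # recovered step function by one node and nothing else
        spacing = 72.0
        edges = np.arange(0.0, 4000.0, spacing)
        rng = np.random.default_rng(5)
        rate = rng.uniform(50.0, 500.0, len(edges) - 1)
        prof_a = deconvolve(
            uir, edges[1:], convolve(uir, edges, rate, edges[1:]),
            edges=edges, regularization=0.0,
        )
        edges_b = np.arange(0.0, 4000.0 + spacing, spacing)
        rate_b = np.concatenate([[0.0], rate])
        prof_b = deconvolve(
            uir, edges_b[1:], convolve(uir, edges_b, rate_b, edges_b[1:]),
            edges=edges_b, regularization=0.0,
        )
        assert prof_b.rate[0] == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(prof_b.rate[1:], prof_a.rate, rtol=1e-6)

    def test_flip_flop_terminal_slope_tracks_input_not_uir(self, uir):
        """With a slowly declining Weibull-type input, the observed terminal
        log-slope is orders of magnitude below the smallest UIR exponent."""
        from depotkit.nca import estimate_lambda_z
        from depotkit.synthetic_data import WeibullInput

        w = WeibullInput(total=3.0e7, A=3500.0, b=1.0)
        edges = make_grid(8928.0)
        rate = np.diff(w.cumulative(edges)) / np.diff(edges)
        t_obs = edges[1:]
        c = convolve(uir, edges, rate, t_obs)
        res = estimate_lambda_z(t_obs[-40:], c[-40:], selection="manual", window=(0, 40))
        assert res.lambda_z is not None
        assert res.lambda_z < min(uir.exponents) / 100.0
        assert res.lambda_z == pytest.approx(1.0 / 3500.0, rel=0.1)


class TestSummaries:
    def _profile(self, rate_ug_day, loaded_mg=100.0, sid="s"):
        edges = make_grid(8928.0)
        rate_ng_h = np.full(len(edges) - 1, rate_ug_day * 1000.0 / 24.0)
        return AbsorptionProfile(
            edges=edges, rate=rate_ng_h, loaded_mass=loaded_mg * 1e6, subject_id=sid
        )

    def test_single_subject_median_is_that_subject(self):
        prof = self._profile(2.0)
        table = summarize_absorption([prof])
        row = table[table.snapshot == "month_6"].iloc[0]
        assert row.rate_ug_day_median == pytest.approx(2.0)
        assert row.rate_ug_day_q1 == pytest.approx(row.rate_ug_day_q3)
        assert row.n == 1

    def test_median_of_three_constant_subjects(self):
        profs = [
            self._profile(v, sid=s) for v, s in ((1.0, "a"), (2.0, "b"), (3.0, "c"))
        ]
        table = summarize_absorption(profs)
        assert table[table.snapshot == "month_1"].iloc[0].rate_ug_day_median == pytest.approx(2.0)

    def test_monotone_declining_truth_puts_burst_at_first_node(self):
        edges = make_grid(8928.0)
        n = len(edges) - 1
        profs = [
            AbsorptionProfile(
                edges=edges,
                rate=np.linspace(1000.0, 10.0, n) * (1 + 0.1 * k),
                loaded_mass=1e8,
                subject_id=f"s{k}",
            )
            for k in range(5)
        ]
        table = summarize_absorption(profs)
        burst = table[table.snapshot == "burst"].iloc[0]
        assert burst.time_day == pytest.approx(1.0)

    def test_fraction_input_requires_loaded_mass(self):
        prof = AbsorptionProfile(edges=[0.0, 24.0], rate=[10.0])
        with pytest.raises(ValueError, match="loaded_mass"):
            _ = prof.fraction_input


class TestRemainingPercent:
    def test_ftc_six_month_case(self):
        # 100 mg loaded, 50.1 mg absorbed -> 49.9% remaining
        assert remaining_percent(100.0, 50.1) == pytest.approx(49.9)

    @pytest.mark.parametrize("absorbed,expected", [(0.0, 100.0), (100.0, 0.0)])
    def test_boundary_cases(self, absorbed, expected):
        assert remaining_percent(100.0, absorbed) == pytest.approx(expected)

    def test_overshoot_warns_not_raises(self):
        with pytest.warns(UserWarning, match="exceeds"):
            assert remaining_percent(100.0, 110.0) == pytest.approx(-10.0)

    def test_nonpositive_load_rejected(self):
        with pytest.raises(ValueError):
            remaining_percent(0.0, 10.0)
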