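from collections import Counter

import numpy as np
import pytest

from depotkit import synthetic_data as syn
from depotkit.deconvolution import convolve
from depotkit.pkdata_io import write_samples_csv


class TestIVSimulation:
    def test_balanced_sparse_design(self):
        data = syn.simulate_iv_study(syn.study_iv_config("BIC", seed=0))
        assert len(data.samples) == 32
        per_tp = Counter(s.time for s in data.samples)
        assert all(n == 4 for n in per_tp.values()) and len(per_tp) == 8
        per_subj = Counter(s.subject_id for s in data.samples)
        assert all(n == 2 for n in per_subj.values()) and len(per_subj) == 16

    def test_noise_free_limit_is_the_biexponential(self):
        cfg = syn.study_iv_config("ISL", seed=0, iiv_sd=0.0, residual_sd=0.0)
        data = syn.simulate_iv_study(cfg)
        for s in data.samples:
            expected = 5275.9 * np.exp(-0.5 * s.time) + 6.3 * np.exp(-0.1 * s.time)
            if expected < cfg.lloq:
                assert s.bql
            else:
                assert s.concentration == pytest.approx(expected, rel=1e-10)

    def test_isl_30h_closed_form_value(self):
        # direct evaluation of A e^{-alpha t} + B e^{-beta t} at t = 30 h
        expected = 5275.9 * np.exp(-0.5 * 30.0) + 6.3 * np.exp(-0.1 * 30.0)
        cfg = syn.study_iv_config("ISL", seed=0, iiv_sd=0.0, residual_sd=0.0)
        data = syn.simulate_iv_study(cfg)
        at_30 = [s for s in data.samples if s.time == 30.0]
        assert at_30 and all(
            s.concentration == pytest.approx(expected, rel=1e-12) for s in at_30
        )

    def test_unbalanceable_design_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            syn.study_iv_config("BIC", n_subjects=15)

    def test_fixed_seed_reproduces_byte_identical_csv(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            write_samples_csv(
                syn.simulate_iv_study(syn.study_iv_config("FTC", seed=42)),
                tmp_path / name,
            )
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


class TestImplantSimulation:
    def test_zero_input_gives_all_blq(self, isl_uir):
        cfg = syn.study_sq_config(
            "ISL", seed=0,
            true_input=syn.ZeroOrderInput(k0=0.0),
            uir=isl_uir, residual_sd=0.0, iiv_sd=0.0,
        )
        data = syn.simulate_implant_study(cfg)
        assert all(s.bql for s in data.samples)

    def test_constant_rate_matches_analytic_infusion_formula(self, isl_uir):
        k0 = 5000.0  # ng/h
        cfg = syn.study_sq_config(
            "ISL", seed=0,
            true_input=syn.ZeroOrderInput(k0=k0),
            uir=isl_uir, residual_sd=0.0, iiv_sd=0.0, n_subjects=1,
        )
        data = syn.simulate_implant_study(cfg)
        c = np.array(isl_uir.coefficients)
        lam = np.array(isl_uir.exponents)
        for s in data.samples:
            expected = k0 * float((c / lam * (1 - np.exp(-lam * s.time))).sum())
            assert s.concentration == pytest.approx(expected, rel=1e-9)

    def test_weibull_input_mass_balance_over_study(self):
        total = 30.0e6  # 30 mg in ng
        w = syn.WeibullInput(total=total, A=500.0, b=1.0)
        horizon = 371.0 * 24.0
        # numeric integral of the rate equals the analytic cumulative
        tt = np.linspace(0, horizon, 200001)
        integral = np.trapezoid(w.rate(tt), tt)
        assert integral == pytest.approx(float(w.cumulative(horizon)), rel=1e-4)
        assert float(w.cumulative(horizon)) == pytest.approx(total, rel=1e-6)

    def test_truncated_arm_via_sampling_days_override(self, isl_uir):
        cfg = syn.study_sq_config(
            "ISL", seed=1, sampling_days=(1.0, 7.0, 14.0, 28.0, 42.0, 56.0)
        )
        data = syn.simulate_implant_study(cfg)
        assert max(s.time for s in data.samples) == 56.0 * 24.0

    def test_overloaded_input_rejected(self, isl_uir):
        with pytest.raises(ValueError, match="loaded mass"):
            syn.study_sq_config(
                "ISL",
                true_input=syn.ZeroOrderInput(k0=1e9),
                loaded_mass_ng=1.0e6,
            )


class TestDissolutionSimulation:
    def test_zero_order_noise_free_equal_masses(self):
        cfg = syn.study_dissolution_config(
            "BIC", seed=0, noise_sd=0.0, n_implants=1
        )
        rel = syn.simulate_dissolution(cfg)
        masses = [r.mass_released for r in rel]
        assert np.allclose(masses, masses[0])

    def test_weibull_b1_reduces_to_first_order_interval_masses(self):
        A = 40.0
        cfg = syn.DissolutionSimConfig(
            analyte="X", model="weibull",
            parameters={"fmax": 1.0, "A": A, "b": 1.0},
            loaded_mass_ug=1000.0, n_implants=1, noise_sd=0.0, seed=0,
        )
        rel = syn.simulate_dissolution(cfg)
        for r in rel:
            expected = 1000.0 * (
                np.exp(-r.interval_start / A) - np.exp(-r.interval_end / A)
            )
            assert r.mass_released == pytest.approx(expected, rel=1e-12)

    def test_26_week_twice_weekly_schedule_has_52_intervals(self):
        cfg = syn.study_dissolution_config("ISL", seed=0, n_implants=1, study_days=182.0)
        rel = syn.simulate_dissolution(cfg)
        assert len(rel) == 52

    def test_invalid_shape_parameter_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            syn.DissolutionSimConfig(
                analyte="X", model="weibull",
                parameters={"fmax": 1.0, "A": -1.0, "b": 1.0},
                loaded_mass_ug=1000.0,
            )


class TestStudyBundle:
    def test_bundle_is_deterministic_under_seed(self):
        b1 = syn.make_study_bundle(seed=5, analytes=("ISL",))
        b2 = syn.make_study_bundle(seed=5, analytes=("ISL",))
        assert b1["dataset"].samples == b2["dataset"].samples
        assert b1["release"]["ISL"] == b2["release"]["ISL"]

    def test_flip_flop_structure_in_generated_sq_profiles(self):
        """Terminal decline of the simulated implant profile is far slower than
        the disposition exponents: the generator produces flip-flop data."""
        from depotkit.nca import estimate_lambda_z
        from depotkit.pkdata_io import impute_blq

        cfg = syn.study_sq_config("ISL", seed=2, residual_sd=0.0, iiv_sd=0.0, n_subjects=1)
        data = impute_blq(syn.simulate_implant_study(cfg))
        t = [s.time for s in data.samples]
        c = [s.concentration for s in data.samples]
        res = estimate_lambda_z(t, c)
        assert res.lambda_z is not None
        assert res.lambda_z < min(cfg.uir.exponents) / 50.0
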