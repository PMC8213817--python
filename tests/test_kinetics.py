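"""Binding-kinetics model evaluation, isotherm and trace fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slbfet as sf
from slbfet.kinetics import transient_discontinuity

from conftest import K1_TRUE, KEQ_TRUE, KM1_TRUE, VMAX_TRUE_MV


class TestLangmuirResponse:
    @pytest.mark.parametrize(
        "conc, keq, vmax, expected",
        [
            (0.0, 1e-9, 9.38, 0.0),                       # no analyte
            (621.9e-12, 621.9e-12, 9.38, 4.69),           # half saturation
            (800e-12, 621.9e-12, 9.38, 5.2774457),        # 9.38*800/1421.9
        ],
    )
    def test_values(self, conc, keq, vmax, expected):
        assert sf.langmuir_response(conc, keq, vmax) == pytest.approx(
            expected, rel=1e-6)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            sf.langmuir_response(-1e-9, 1e-9, 9.38)
        with pytest.raises(ValueError):
            sf.langmuir_response(1e-9, 0.0, 9.38)

    @settings(derandomize=True, max_examples=200)
    @given(
        conc=st.floats(1e-13, 1e-6),
        factor=st.floats(1.0001, 100.0),
        keq=st.floats(1e-12, 1e-8),
    )
    def test_monotone_and_bounded(self, conc, factor, keq):
        lo = sf.langmuir_response(conc, keq, VMAX_TRUE_MV)
        hi = sf.langmuir_response(conc * factor, keq, VMAX_TRUE_MV)
        assert 0.0 <= lo < hi < VMAX_TRUE_MV


class TestTraceModel:
    def test_zero_at_t0(self, kinetic_params):
        assert sf.trace_model(0.0, kinetic_params, 800e-12) == 0.0

    def test_saturates_at_vmax_without_transient(self, kinetic_params):
        p = sf.KineticParams(k1=K1_TRUE, k_minus1=KM1_TRUE,
                             V_max_mV=VMAX_TRUE_MV, V_p_mV=0.0)
        assert sf.trace_model(1e6, p, 800e-12) == pytest.approx(
            VMAX_TRUE_MV, rel=1e-9)

    def test_observed_rate_constant(self, kinetic_params):
        # k1[A] + k_-1 = 1.64e7*8e-10 + 1.02e-2 = 2.332e-2 s^-1
        p = sf.KineticParams(k1=K1_TRUE, k_minus1=KM1_TRUE,
                             V_max_mV=1.0, V_p_mV=0.0)
        t = np.linspace(1.0, 100.0, 50)
        v = sf.trace_model(t, p, 800e-12)
        k_obs = -np.log(1.0 - v) / t
        assert np.allclose(k_obs, 2.332e-2, rtol=1e-9)

    def test_equilibrium_fraction_plateau_matches_isotherm(self, kinetic_params):
        p = sf.KineticParams(k1=K1_TRUE, k_minus1=KM1_TRUE,
                             V_max_mV=VMAX_TRUE_MV, V_p_mV=0.0)
        plateau = sf.trace_model(1e7, p, 800e-12, equilibrium_fraction=True)
        assert plateau == pytest.approx(
            sf.langmuir_response(800e-12, KEQ_TRUE, VMAX_TRUE_MV), rel=1e-9)

    def test_continuous_branch_matching(self, kinetic_params):
        eps = 1e-9
        before = sf.trace_model(kinetic_params.T_s - eps, kinetic_params, 800e-12)
        after = sf.trace_model(kinetic_params.T_s + eps, kinetic_params, 800e-12)
        assert after == pytest.approx(before, abs=1e-6)

    def test_verbatim_branches_discontinuous_and_reported(self, kinetic_params):
        eps = 1e-9
        before = sf.trace_model(kinetic_params.T_s - eps, kinetic_params,
                                800e-12, continuous=False)
        after = sf.trace_model(kinetic_params.T_s + eps, kinetic_params,
                               800e-12, continuous=False)
        jump = transient_discontinuity(kinetic_params)
        assert jump > 0
        assert abs(after - before) == pytest.approx(jump, rel=1e-6)


class TestRatesAndMaxResponse:
    def test_keq_reproduces_printed_equilibrium_constant(self):
        # 1.02e-2 / 1.64e7 = 6.2195e-10 M, the printed 621.9 pM
        assert sf.keq_from_rates(1.64e7, 1.02e-2) == pytest.approx(
            621.9e-12, rel=1e-3)

    @pytest.mark.parametrize("k1, km1, expected", [
        (5.0, 0.0, 0.0),
        (3.7, 3.7, 1.0),
    ])
    def test_limits(self, k1, km1, expected):
        assert sf.keq_from_rates(k1, km1) == expected

    def test_zero_association_rejected(self):
        with pytest.raises(ValueError):
            sf.keq_from_rates(0.0, 1e-2)

    def test_max_response_from_printed_fit_values(self):
        sys = sf.BindingSystem(q_A_C=2.59e-23, B_max=1.74e8, C_TG_F=0.37e-12)
        assert sf.max_response(sys) == pytest.approx(12.18, rel=1e-3)
        # effective charge in elementary units: ~1.61e-4 e
        assert sys.q_A_electrons == pytest.approx(1.6165e-4, rel=1e-4)

    def test_no_binding_sites_gives_zero(self):
        sys = sf.BindingSystem(q_A_C=2.59e-23, B_max=0.0, C_TG_F=0.37e-12)
        assert sf.max_response(sys) == 0.0


class TestFitIsotherm:
    def test_noiseless_round_trip(self, kinetic_params):
        pts = sf.gen_titration(kinetic_params, np.logspace(-10, -7, 12),
                               sf.NoiseSpec(voltage_sigma_mV=0.0))
        fit = sf.fit_isotherm(pts)
        assert fit.success
        assert fit.K_eq_M == pytest.approx(KEQ_TRUE, rel=1e-3)
        assert fit.V_max_mV == pytest.approx(VMAX_TRUE_MV, rel=1e-3)

    def test_all_zero_responses_flagged(self):
        fit = sf.fit_isotherm([(1e-10, 0.0), (1e-9, 0.0), (1e-8, 0.0)])
        assert not fit.success
        assert fit.V_max_mV == pytest.approx(0.0, abs=1e-9)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            sf.fit_isotherm([(1e-9, 1.0), (1e-8, 2.0)])

    def test_median_error_under_noise(self, kinetic_params):
        """5% noise, 50 seeds: median |K_eq error| stays below 10%."""
        errs = []
        for seed in range(50):
            pts = sf.gen_titration(
                kinetic_params, np.logspace(-10, -7, 12),
                sf.NoiseSpec(voltage_sigma_mV=0.05 * VMAX_TRUE_MV, seed=seed))
            fit = sf.fit_isotherm(pts)
            errs.append(abs(fit.K_eq_M - KEQ_TRUE) / KEQ_TRUE)
        assert np.median(errs) < 0.10


class TestFitTrace:
    def test_noiseless_exact_recovery(self, kinetic_params):
        inj = [sf.InjectionEvent(0.0, 800e-12, "avidin")]
        trace = sf.gen_binding_trace(kinetic_params, inj, 600.0, 1.0,
                                     sf.NoiseSpec(voltage_sigma_mV=0.0))
        fit = sf.fit_trace(trace, fixed={"K_eq_M": KEQ_TRUE})
        p = fit.params
        for name in ("k1", "k_minus1", "V_max_mV", "V_p_mV",
                     "tau1_s", "tau2_s", "T_s"):
            assert getattr(p, name) == pytest.approx(
                getattr(kinetic_params, name), rel=1e-4), name

    def test_control_trace_has_no_response(self, kinetic_params):
        """A non-binding control analyte (CTxB analog) fits to V_max ~ 0."""
        p0 = sf.KineticParams(k1=K1_TRUE, k_minus1=KM1_TRUE, V_max_mV=0.0,
                              V_p_mV=0.0)
        inj = [sf.InjectionEvent(0.0, 800e-12, "CTxB-control")]
        trace = sf.gen_binding_trace(p0, inj, 300.0, 1.0,
                                     sf.NoiseSpec(voltage_sigma_mV=0.05, seed=3))
        fit = sf.fit_trace(trace, fixed={"K_eq_M": KEQ_TRUE})
        assert abs(fit.params.V_max_mV) < 0.2

    def test_insufficient_post_injection_data_rejected(self, kinetic_params):
        inj = [sf.InjectionEvent(90.0, 800e-12, "avidin")]
        trace = sf.gen_binding_trace(kinetic_params, inj, 100.0, 1.0,
                                     sf.NoiseSpec(voltage_sigma_mV=0.0))
        with pytest.raises(ValueError, match="insufficient"):
            sf.fit_trace(trace, fixed={"K_eq_M": KEQ_TRUE})

    def test_unconstrained_rates_rejected(self, kinetic_params):
        inj = [sf.InjectionEvent(0.0, 800e-12, "avidin")]
        trace = sf.gen_binding_trace(kinetic_params, inj, 600.0, 1.0,
                                     sf.NoiseSpec(voltage_sigma_mV=0.0))
        with pytest.raises(ValueError, match="identifiable"):
            sf.fit_trace(trace)

    def test_plateau_consistent_with_isotherm(self, kinetic_params):
        """Fitted trace plateau reproduces the equilibrium isotherm value."""
        inj = [sf.InjectionEvent(0.0, 800e-12, "avidin")]
        trace = sf.gen_binding_trace(kinetic_params, inj, 600.0, 1.0,
                                     sf.NoiseSpec(voltage_sigma_mV=0.05, seed=7))
        fit = sf.fit_trace(trace, fixed={"K_eq_M": KEQ_TRUE})
        plateau = sf.langmuir_response(800e-12, KEQ_TRUE, fit.params.V_max_mV)
        expected = sf.langmuir_response(800e-12, KEQ_TRUE, VMAX_TRUE_MV)
        assert plateau == pytest.approx(expected, rel=0.05)


class TestCurrentToVoltage:
    def test_linear_transfer_inverts_exactly(self):
        gm = 1e-4
        transfer = sf.gen_transfer_curve(gm, (-0.1, 0.1), 101, shape="linear")
        t = np.arange(5.0)
        v_true = np.array([-0.05, -0.02, 0.0, 0.03, 0.08])
        i = np.interp(v_true, transfer.v_tg_V, transfer.i_d_A)
        trace = sf.TimeTrace(t_s=t, i_d_A=i)
        out = sf.current_to_voltage(trace, transfer)
        assert np.allclose(out.v_tg_mV, v_true * 1e3, atol=1e-9)

    def test_sigmoid_round_trip_at_grid_points(self):
        transfer = sf.gen_transfer_curve(1e-4, (-0.1, 0.1), 201, shape="sigmoid")
        v_true = transfer.v_tg_V[20:-20:10]
        i = np.interp(v_true, transfer.v_tg_V, transfer.i_d_A)
        trace = sf.TimeTrace(t_s=np.arange(float(len(i))), i_d_A=i)
        out = sf.current_to_voltage(trace, transfer)
        assert np.max(np.abs(out.v_tg_mV * 1e-3 - v_true)) < 1e-9

    def test_out_of_range_current_reports_sample(self):
        transfer = sf.gen_transfer_curve(1e-4, (-0.1, 0.1), 101)
        trace = sf.TimeTrace(t_s=np.array([0.0, 1.0]),
                             i_d_A=np.array([2e-6, 1.0]))
        with pytest.raises(ValueError, match="sample 1"):
            sf.current_to_voltage(trace, transfer)
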