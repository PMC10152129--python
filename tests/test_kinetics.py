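import numpy as np
import pytest
from scipy.integrate import quad

from lungpet.core import TimeActivityCurve, ValidationError, make_frame_schedule, truncate_tac
from lungpet.input_function import PlasmaInput
from lungpet.kinetics import (
    KineticFit,
    KineticParams,
    aic,
    fit_compartment,
    impulse_response_1tc,
    impulse_response_2tc,
    logan_fit,
    model_tac,
    select_model,
)
from lungpet.synthetic import simulate_subject


class TestImpulseResponse:
    def test_initial_value_is_k1(self, canonical_params):
        assert impulse_response_2tc(canonical_params, 0.0) == pytest.approx(
            canonical_params.K1, rel=1e-12
        )

    def test_k3_zero_reduces_to_one_tissue(self):
        kp = KineticParams(K1=1.5, k2=0.8, k3=0.0, k4=0.7)
        t = np.linspace(0.0, 60.0, 301)
        np.testing.assert_allclose(
            impulse_response_2tc(kp, t), impulse_response_1tc(kp, t), rtol=1e-9
        )

    def test_integral_equals_total_distribution_volume(self, canonical_params):
        # independent quadrature oracle for int_0^inf h(t) dt = V_T
        val, _ = quad(lambda t: impulse_response_2tc(canonical_params, t),
                      0.0, np.inf, limit=200)
        assert val == pytest.approx(canonical_params.vt, rel=1e-8)

    def test_non_negative(self, canonical_params):
        t = np.linspace(0.0, 120.0, 2001)
        assert np.all(impulse_response_2tc(canonical_params, t) >= 0.0)

    def test_requires_reversible_rates(self):
        with pytest.raises(ValidationError):
            impulse_response_2tc(KineticParams(K1=1.0, k2=1.0), 1.0)


class TestModelTac:
    def test_zero_params_zero_tac(self, analytic_plasma, canonical_subject):
        _, blood, _ = canonical_subject
        kp = KineticParams(K1=0.0, k2=1.0, vB=0.0)
        out = model_tac(kp, analytic_plasma, blood, blood.schedule, "1tc")
        assert np.all(out.values == 0.0)

    def test_blood_term_only(self, analytic_plasma, canonical_subject):
        _, blood, _ = canonical_subject
        kp = KineticParams(K1=0.0, k2=1.0, vB=0.15)
        out = model_tac(kp, analytic_plasma, blood, blood.schedule, "2tc")
        np.testing.assert_allclose(out.values, 0.15 * blood.values, rtol=1e-12)

    def test_forward_model_reproduces_simulated_lung(
        self, canonical_params, canonical_subject, analytic_plasma
    ):
        lung, blood, _ = canonical_subject
        out = model_tac(canonical_params, analytic_plasma, blood,
                        lung.schedule, "2tc")
        np.testing.assert_allclose(out.values, lung.values, rtol=1e-6, atol=1e-8)

    def test_schedule_mismatch_rejected(self, analytic_plasma, canonical_subject):
        _, blood, _ = canonical_subject
        other = make_frame_schedule([(10, 7)])
        with pytest.raises(ValidationError):
            model_tac(KineticParams(K1=1.0, k2=1.0, k3=0.5, k4=0.5, vB=0.1),
                      analytic_plasma, blood, other, "2tc")


class TestFitCompartment:
    def test_noiseless_round_trip_recovers_parameters(
        self, canonical_params, canonical_subject, analytic_plasma
    ):
        lung, blood, _ = canonical_subject
        fit = fit_compartment(lung, analytic_plasma, blood, "2tc")
        p = fit.params
        for name in ("K1", "k2", "k3", "k4", "vB"):
            est, true = getattr(p, name), getattr(canonical_params, name)
            assert abs(est - true) / true < 0.01, name
        assert fit.vt == pytest.approx(canonical_params.vt, rel=0.01)
        assert fit.bp_nd == pytest.approx(canonical_params.bp_nd, rel=0.01)
        assert fit.converged

    def test_macro_parameter_identity_holds_exactly(
        self, canonical_subject, analytic_plasma
    ):
        lung, blood, _ = canonical_subject
        fit = fit_compartment(lung, analytic_plasma, blood, "2tc")
        assert fit.vt == pytest.approx(fit.k1_over_k2 * (1.0 + fit.bp_nd), rel=1e-12)

    def test_fixed_and_floating_vb_agree_at_true_value(
        self, canonical_subject, analytic_plasma
    ):
        lung, blood, _ = canonical_subject
        fixed = fit_compartment(lung, analytic_plasma, blood, "2tc",
                                vb_mode=("fixed", 0.15))
        floating = fit_compartment(lung, analytic_plasma, blood, "2tc",
                                   vb_mode=("floating", 0.05, 0.3))
        assert fixed.vt == pytest.approx(floating.vt, rel=1e-3)
        assert fixed.bp_nd == pytest.approx(floating.bp_nd, rel=1e-3)
        assert fixed.n_params == 4 and floating.n_params == 5

    def test_nested_model_equivalence_on_1tc_data(self, input_model, analytic_plasma):
        kp = KineticParams(K1=2.0, k2=2.0, vB=0.15)
        lung, blood, _ = simulate_subject(kp, input_model)
        f1 = fit_compartment(lung, analytic_plasma, blood, "1tc")
        f2 = fit_compartment(lung, analytic_plasma, blood, "2tc")
        assert f1.params.K1 == pytest.approx(kp.K1, rel=1e-3)
        assert f1.params.k2 == pytest.approx(kp.k2, rel=1e-3)
        assert f1.params.vB == pytest.approx(kp.vB, rel=1e-3)
        # the richer model agrees on the shared parameters and on V_T
        assert f2.vt == pytest.approx(f1.vt, rel=5e-3)
        assert f2.params.vB == pytest.approx(kp.vB, rel=5e-3)

    def test_default_window_is_first_forty_minutes(
        self, canonical_subject, analytic_plasma
    ):
        lung, blood, _ = canonical_subject
        fit = fit_compartment(lung, analytic_plasma, blood, "2tc")
        assert fit.n_frames == 46  # frames ending within 40 min

    def test_non_finite_tac_rejected(self):
        # the domain type itself refuses non-finite activity values
        s = make_frame_schedule([(5, 60)])
        with pytest.raises(ValidationError):
            TimeActivityCurve(s, np.array([1.0, 2.0, np.nan, 1.0, 0.5]), noisy=True)


class TestLogan:
    def test_exact_linear_data(self):
        # constant lung and constant plasma: y(T) = T - c, x(T) = (T - c)/1.2
        s = make_frame_schedule([(30, 120)])
        lung = TimeActivityCurve(s, np.full(30, 5.0))
        t = np.array([1.0, 3600.0])
        plasma = PlasmaInput(t, np.full(2, 5.0 / 1.2))
        res = logan_fit(lung, plasma, t_star_min=10.0)
        assert res.slope == pytest.approx(1.2, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_near_vt_without_blood_signal(self, input_model, analytic_plasma):
        kp = KineticParams(K1=2.0, k2=4.0, k3=1.2, k4=1.0, vB=0.0)
        lung, _, _ = simulate_subject(kp, input_model)
        res = logan_fit(lung, analytic_plasma, t_star_min=10.0)
        assert abs(res.slope - kp.vt) / kp.vt < 0.05
        assert res.n_points_used >= 3

    def test_bias_shrinks_with_acquisition_duration(self, input_model, analytic_plasma):
        kp = KineticParams(K1=2.0, k2=4.0, k3=1.2, k4=1.0, vB=0.0)
        lung, _, _ = simulate_subject(kp, input_model)
        biases = [
            abs(logan_fit(truncate_tac(lung, m * 60.0), analytic_plasma, 5.0).slope
                - kp.vt)
            for m in (20, 40, 60)
        ]
        assert biases[0] >= biases[1] >= biases[2]

    def test_too_few_late_frames_rejected(self, canonical_subject, analytic_plasma):
        lung, _, _ = canonical_subject
        with pytest.raises(ValidationError):
            logan_fit(lung, analytic_plasma, t_star_min=55.0)


class TestAic:
    def test_unit_mean_square_gives_two_k(self):
        assert aic(rss=46.0, n_frames=46, n_params=5) == pytest.approx(10.0)

    def test_doubling_rss_adds_n_log_two(self):
        a1 = aic(10.0, 46, 5)
        a2 = aic(20.0, 46, 5)
        assert a2 - a1 == pytest.approx(46 * np.log(2.0))

    def test_perfect_fit_warns_minus_inf(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert aic(0.0, 46, 5) == -np.inf

    def test_requires_more_frames_than_params(self):
        with pytest.raises(ValidationError):
            aic(1.0, 5, 5)


def _dummy_fit(aic_value, n_params, n_frames=46, tag="2tc"):
    kp = KineticParams(K1=1.0, k2=1.0, k3=0.5, k4=0.5, vB=0.1)
    return KineticFit(params=kp, vt=2.0, k1_over_k2=1.0, bp_nd=1.0, rss=1.0,
                      n_frames=n_frames, n_params=n_params, aic=aic_value,
                      model_tag=tag, converged=True, n_starts_used=10)


class TestSelectModel:
    def test_lower_aic_wins(self):
        best = select_model([_dummy_fit(184.0, 6), _dummy_fit(295.0, 4, tag="1tc")])
        assert best.aic == 184.0

    def test_tie_goes_to_fewer_parameters(self):
        best = select_model([_dummy_fit(100.0, 6), _dummy_fit(100.0, 4, tag="1tc")])
        assert best.n_params == 4

    def test_single_fit_returned(self):
        only = _dummy_fit(50.0, 4)
        assert select_model([only]) is only

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValidationError):
            select_model([_dummy_fit(1.0, 4, n_frames=46),
                          _dummy_fit(2.0, 4, n_frames=50)])
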