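"""Closed-form compartment kinetics against independent numerical oracles."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petkin import (
    BloodCurve,
    InvalidInputError,
    KineticParams,
    ModelSpec,
    compartment_curves,
    fit_model,
    frame_weights,
    ki_macro,
    model_tac,
    model_values,
)

from conftest import random_blood, random_params


def ode_oracle(params, input_curve, t_eval, rtol=1e-10):
    """Reference C1/C2 by direct integration of the mass-balance ODEs."""

    def rhs(t, y):
        cp = float(input_curve.at(t))
        c1, c2 = y
        return [
            params.K1 * cp - (params.k2 + params.k3) * c1 + params.k4 * c2,
            params.k3 * c1 - params.k4 * c2,
        ]

    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [0.0, 0.0],
        t_eval=t_eval, rtol=rtol, atol=1e-13, method="LSODA",
    )
    assert sol.success
    return sol.y[0], sol.y[1]


class TestForwardModel:
    def test_no_delivery_no_blood_gives_zero(self, blood, schedule):
        params = KineticParams(vb=0.0, K1=0.0, k2=0.3)
        assert np.all(model_tac(params, blood, schedule).values == 0.0)

    def test_trapping_limit_with_constant_input_is_linear_ramp(self):
        # k2 = 0, vb = 0, constant input c: C(t) = K1 c t, frame averages at midpoints
        from petkin import FramingSchedule

        c, K1 = 2.0, 0.1
        curve = BloodCurve(amplitudes=[c], rates=[0.0])
        sched = FramingSchedule.from_pairs([(0, 1), (1, 3), (3, 10)])
        vals = model_values(KineticParams(vb=0.0, K1=K1, k2=0.0), curve, sched)
        assert np.allclose(vals, K1 * c * sched.mid, rtol=1e-12)

    def test_2t5p_with_k4_zero_equals_2t4p(self, blood, schedule):
        base = dict(vb=0.2, K1=0.3, k2=0.15, k3=0.02)
        v5 = model_values(KineticParams(**base, k4=0.0), blood, schedule)
        v4 = model_values(KineticParams(**base), blood, schedule)
        assert np.array_equal(v5, v4)

    def test_closed_form_matches_ode_oracle_on_random_draws(self, schedule):
        rng = np.random.default_rng(2024)
        t = np.linspace(0.0, 2940.0, 25)[1:]
        for _ in range(100):
            params = random_params(rng)
            curve = random_blood(rng)
            cc = compartment_curves(params, curve, t)
            c1_ref, c2_ref = ode_oracle(params, curve, t)
            scale = np.max(np.abs(c1_ref) + np.abs(c2_ref))
            assert np.max(np.abs(cc.c1 - c1_ref)) <= 1e-6 * scale
            assert np.max(np.abs(cc.c2 - c2_ref)) <= 1e-6 * scale

    def test_compartment_sum_equals_tissue_part(self, blood, schedule, bone_marrow_params):
        from petkin.compartments import tissue_mix

        t = schedule.mid
        cc = compartment_curves(bone_marrow_params, blood, t)
        assert np.allclose(cc.total_tissue, tissue_mix(bone_marrow_params, blood)(t), rtol=1e-12)

    def test_mass_balance_residual_by_finite_differences(self, blood, bone_marrow_params):
        p = bone_marrow_params
        t = np.linspace(1.0, 2000.0, 50)
        h = 1e-3
        up = compartment_curves(p, blood, t + h)
        dn = compartment_curves(p, blood, t - h)
        mid = compartment_curves(p, blood, t)
        # serial two-tissue mass balance: d(C1+C2)/dt = K1 Cp - k2 C1
        d_total = (up.total_tissue - dn.total_tissue) / (2 * h)
        expected = p.K1 * blood.at(t) - p.k2 * mid.c1
        assert np.allclose(d_total, expected, rtol=1e-4)

    def test_k3_zero_means_empty_second_compartment(self, blood):
        cc = compartment_curves(KineticParams(vb=0.1, K1=0.2, k2=0.1), blood, np.linspace(0, 100, 20))
        assert np.all(cc.c2 == 0.0)

    def test_bound_compartment_has_single_interior_peak(self, blood):
        from petkin import REGION_ARCHETYPES

        t = np.linspace(1.0, 2940.0, 600)
        c2 = compartment_curves(REGION_ARCHETYPES["spleen"], blood, t).c2
        i = int(np.argmax(c2))
        assert 0 < i < len(t) - 1  # interior maximum
        # single peak: rises before, falls after
        assert np.all(np.diff(c2[: i + 1]) > 0)
        assert np.all(np.diff(c2[i + 1 :]) < 0)

    def test_linearity_in_the_input(self, blood, schedule, bone_marrow_params):
        scaled = BloodCurve(amplitudes=3.0 * blood.amplitudes, rates=blood.rates)
        v = model_values(bone_marrow_params, blood, schedule)
        assert np.allclose(model_values(bone_marrow_params, scaled, schedule), 3.0 * v, rtol=1e-12)


class TestFrameWeights:
    def test_decay_halves_weight_after_one_half_life(self):
        from petkin import FramingSchedule

        hl_min = 78.4 * 60
        # equal-duration frames whose midpoints are exactly one half-life apart
        sched = FramingSchedule.from_pairs([(0, 1), (hl_min, hl_min + 1)])
        w = frame_weights(sched, late_downweight=1.0)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-9)

    def test_late_sessions_downweighted_by_factor(self, schedule):
        w1 = frame_weights(schedule, late_downweight=1.0)
        w10 = frame_weights(schedule, late_downweight=10.0)
        # before normalization the late frames drop tenfold relative to dynamic ones
        ratio_late = (w1[46:] / w1[:46].mean()) / (w10[46:] / w10[:46].mean())
        assert np.allclose(ratio_late, 10.0, rtol=1e-9)

    def test_study_weights_follow_duration_decay_and_session(self, schedule):
        w = frame_weights(schedule)
        lam = np.log(2) / (78.4 * 60)
        raw = schedule.duration * np.exp(-lam * schedule.mid)
        # dynamic frames keep the duration*decay ordering
        assert np.array_equal(np.argsort(w[:46]), np.argsort(raw[:46]))
        # the 48-h frame weighs less than the 6-h frame
        assert w[47] < w[46]
        # the down-weighting costs the late frames a factor 10 relative to
        # what duration and decay alone would give them
        assert w[46] / w[45] == pytest.approx(raw[46] / raw[45] / 10.0, rel=1e-9)
        assert w.sum() == pytest.approx(len(schedule))


class TestKiMacro:
    @pytest.mark.parametrize(
        "K1,k2,k3,expected",
        [(0.2, 0.1, 0.1, 0.1), (0.2, 0.1, 0.0, 0.0), (0.2, 0.0, 0.05, 0.2)],
    )
    def test_formula_and_limits(self, K1, k2, k3, expected):
        assert ki_macro(KineticParams(K1=K1, k2=k2, k3=k3)) == pytest.approx(expected)

    def test_degenerate_no_exchange(self):
        assert ki_macro(KineticParams(K1=0.5)) == 0.0


class TestModelFitting:
    def test_noiseless_round_trip_recovers_parameters(self, blood, schedule, bone_marrow_params):
        tac = model_tac(bone_marrow_params, blood, schedule)
        fit = fit_model(tac, blood, ModelSpec(model="2T5P"))
        assert fit.converged
        for name in ("vb", "K1", "k2", "k3", "k4"):
            true = getattr(bone_marrow_params, name)
            assert abs(getattr(fit.params, name) - true) / true < 1e-3
        assert fit.ki == pytest.approx(ki_macro(bone_marrow_params), rel=1e-3)

    def test_spleen_fit_keeps_vb_fixed_at_04(self, blood, schedule):
        from petkin import REGION_ARCHETYPES

        tac = model_tac(REGION_ARCHETYPES["spleen"], blood, schedule)
        fit = fit_model(tac, blood, ModelSpec(model="2T5P", fixed={"vb": 0.4}))
        assert fit.params.vb == 0.4
        assert "vb" in fit.params.fixed
        assert fit.n_free == 4

    def test_nested_model_wrss_monotone_on_noisy_data(self, blood, schedule, bone_marrow_params):
        rng = np.random.default_rng(7)
        clean = model_values(bone_marrow_params, blood, schedule)
        for i in range(3):
            noisy = np.clip(clean * (1 + 0.05 * rng.normal(size=clean.shape)), 0, None)
            tac = model_tac(bone_marrow_params, blood, schedule).with_values(noisy)
            w = {m: fit_model(tac, blood, ModelSpec(model=m), seed=i).wrss
                 for m in ("1T3P", "2T4P", "2T5P")}
            assert w["2T5P"] <= w["2T4P"] * (1 + 1e-9)
            assert w["2T4P"] <= w["1T3P"] * (1 + 1e-9)

    def test_negative_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParams(K1=-0.1)
        with pytest.raises(InvalidInputError):
            KineticParams(vb=1.5)

    def test_fixed_value_outside_bounds_rejected(self):
        with pytest.raises(InvalidInputError):
            ModelSpec(model="2T5P", fixed={"vb": 0.9})
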