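"""Sensitivity curves, parameter correlations, noise scale, Monte-Carlo bias."""
import numpy as np
import pytest

from petkin import (
    InvalidInputError,
    KineticParams,
    ModelSpec,
    REGION_ARCHETYPES,
    TissueTAC,
    correlation_matrix,
    estimate_noise_scale,
    model_tac,
    normalized_sensitivity,
    simulate_bias_sd,
)
from petkin.compartments import frame_weights, model_values
from petkin.identifiability import noise_sigma


class TestNormalizedSensitivity:
    def test_k1_sensitivity_is_one_for_bloodless_1t(self, blood, schedule):
        # with vb = 0 the 1T model is proportional to K1, so S_K1 = 1 everywhere
        params = KineticParams(vb=0.0, K1=0.1, k2=0.05)
        sens = normalized_sensitivity(params, blood, schedule, model="1T3P")
        assert np.allclose(sens["K1"], 1.0, atol=1e-6)

    def test_fixed_parameters_excluded(self, blood, schedule):
        params = KineticParams(vb=0.4, K1=1.5, k2=0.85, k3=0.1, k4=0.001, fixed={"vb"})
        sens = normalized_sensitivity(params, blood, schedule, model="2T5P")
        assert set(sens) == {"K1", "k2", "k3", "k4"}

    def test_k4_sensitivity_grows_across_sessions(self, blood, schedule):
        sens = normalized_sensitivity(REGION_ARCHETYPES["spleen"], blood, schedule, model="2T5P")
        s_k4 = np.abs(sens["k4"])
        # magnitude at the session ends: 90 min < 6 h < 48 h
        assert s_k4[45] < s_k4[46] < s_k4[47]

    def test_finite_difference_matches_1t_closed_form(self, blood, schedule):
        # 1T: dC/dk2 has the closed form -(K1 t e^{-k2 t}) convolved with Cp;
        # check against an independent (complex-step free) richardson estimate
        params = KineticParams(vb=0.1, K1=0.2, k2=0.1)
        sens = normalized_sensitivity(params, blood, schedule, model="1T3P")
        base = model_values(params, blood, schedule)
        h = 1e-6 * params.k2
        up = model_values(params.with_updates(k2=params.k2 + h), blood, schedule)
        dn = model_values(params.with_updates(k2=params.k2 - h), blood, schedule)
        ref = (up - dn) / (2 * h) * params.k2 / base
        assert np.allclose(sens["k2"], ref, rtol=1e-5, atol=1e-8)


class TestCorrelationMatrix:
    def test_well_formed(self, blood, schedule, bone_marrow_params):
        w = frame_weights(schedule)
        res = correlation_matrix(bone_marrow_params, blood, schedule, w, model="2T5P")
        m = res.matrix
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert np.all(np.abs(m) <= 1.0)

    def test_spleen_regime_couples_vb_and_k1(self, blood, schedule):
        w = frame_weights(schedule)
        res = correlation_matrix(REGION_ARCHETYPES["spleen"], blood, schedule, w, model="2T5P")
        i = res.param_names.index("vb")
        j = res.param_names.index("K1")
        assert abs(res.matrix[i, j]) > 0.9

    def test_orthogonal_jacobian_gives_identity(self):
        # the correlation algebra itself, on a constructed orthogonal design
        from petkin.identifiability import CorrelationResult

        jac = np.array([[1.0, 0.0], [0.0, 2.0], [0.0, 0.0]])
        w = np.ones(3)
        m = jac.T @ (w[:, None] * jac)
        cov = np.linalg.pinv(m)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        assert np.allclose(corr, np.eye(2))


class TestNoiseScale:
    def test_zero_for_perfect_agreement(self, blood, schedule, bone_marrow_params):
        modeled = model_tac(bone_marrow_params, blood, schedule)
        assert estimate_noise_scale(modeled, modeled) == 0.0

    def test_scale_equivariance(self, blood, schedule, bone_marrow_params):
        modeled = model_tac(bone_marrow_params, blood, schedule)
        rng = np.random.default_rng(5)
        resid = rng.normal(size=len(schedule)) * 0.01 * modeled.values
        tac1 = modeled.with_values(np.clip(modeled.values + resid, 1e-9, None))
        tac2 = modeled.with_values(np.clip(modeled.values + 2 * resid, 1e-9, None))
        s1 = estimate_noise_scale(tac1, modeled)
        s2 = estimate_noise_scale(tac2, modeled)
        assert s2 == pytest.approx(2 * s1, rel=1e-2)

    def test_recovers_generating_scale(self, blood, schedule, bone_marrow_params):
        true_sc = 0.05
        clean = model_values(bone_marrow_params, blood, schedule)
        sigma = noise_sigma(clean, schedule, true_sc)
        modeled = model_tac(bone_marrow_params, blood, schedule)
        rng = np.random.default_rng(12)
        estimates = [
            estimate_noise_scale(
                modeled.with_values(np.clip(clean + rng.normal(size=clean.shape) * sigma, 0, None)),
                modeled,
            )
            for _ in range(100)
        ]
        assert abs(np.mean(estimates) - true_sc) / true_sc < 0.15


class TestMonteCarlo:
    def test_noiseless_replicates_have_no_bias_or_spread(self, blood, schedule, bone_marrow_params):
        rep = simulate_bias_sd(
            bone_marrow_params, blood, schedule, ModelSpec(model="2T5P"),
            noise_scale=0.0, n_reps=3, seed=2,
        )
        assert np.all(np.abs(rep.bias_pct) < 0.1)
        assert np.all(rep.sd_pct < 0.1)
        assert rep.n_failed == 0 and not rep.unreliable

    def test_report_is_deterministic_for_fixed_seed(self, blood, schedule, bone_marrow_params):
        kwargs = dict(noise_scale=0.05, n_reps=5, seed=33)
        r1 = simulate_bias_sd(bone_marrow_params, blood, schedule, ModelSpec(model="2T5P"), **kwargs)
        r2 = simulate_bias_sd(bone_marrow_params, blood, schedule, ModelSpec(model="2T5P"), **kwargs)
        assert np.array_equal(r1.estimates, r2.estimates)
        assert np.array_equal(r1.bias_pct, r2.bias_pct)

    def test_rmse_identity_and_low_bias_at_calibrated_noise(self, blood, schedule, bone_marrow_params):
        rep = simulate_bias_sd(
            bone_marrow_params, blood, schedule, ModelSpec(model="2T5P"),
            noise_scale=0.05, n_reps=20, seed=8,
        )
        assert np.allclose(rep.rmse_pct**2, rep.bias_pct**2 + rep.sd_pct**2, rtol=1e-9)
        for name in ("K1", "k2", "k3"):
            assert abs(rep.bias_pct[rep.param_names.index(name)]) < 5.0

    def test_too_few_replicates_rejected(self, blood, schedule, bone_marrow_params):
        with pytest.raises(InvalidInputError):
            simulate_bias_sd(
                bone_marrow_params, blood, schedule, ModelSpec(model="2T5P"),
                noise_scale=0.05, n_reps=1, seed=0,
            )
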