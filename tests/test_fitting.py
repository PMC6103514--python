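"""Least-squares and errors-in-variables estimation."""
import numpy as np
import pandas as pd
import pytest

from canopyn.fitting import (
    EivConfig,
    estimate_sigma,
    fit_eiv,
    fit_family_eiv,
    fit_family_lsm,
    fit_lsm,
)
from canopyn.models import ModelSpec
from canopyn.synthetic import (
    default_study_model,
    default_study_spec,
    family_recovery_spec,
    generate_samples,
)
from conftest import deming_closed_form, effective_coefficients


class TestLsmLinearFamilies:
    def test_noiseless_interpolation(self, rng):
        X = rng.uniform(1, 5, (40, 3))
        gs = rng.uniform(0.2, 1.0, 40)
        y = 2.0 + 1.5 * X[:, 0] - 0.7 * X[:, 1] + 0.3 * X[:, 2] + 4.0 * gs
        p, sse, conv, _ = fit_family_lsm("linear", X, y, gs)
        assert conv
        assert np.allclose(p["a"], [1.5, -0.7, 0.3], atol=1e-8)
        assert p["b0"] == pytest.approx(2.0, abs=1e-8)
        assert p["b1"] == pytest.approx(4.0, abs=1e-8)
        assert sse < 1e-16

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        X = rng.uniform(1, 5, (30, 3))
        y = 1.0 + X @ [0.5, -1.0, 2.0] + rng.normal(0, 0.3, 30)
        p, *_ = fit_family_lsm("linear", X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit().params
        assert np.allclose(p["a"], ref[1:], atol=1e-9)
        assert p["b0"] == pytest.approx(ref[0], abs=1e-9)

    def test_constant_response(self, rng):
        X = rng.uniform(1, 5, (20, 3))
        y = np.full(20, 6.0)
        p, *_ = fit_family_lsm("linear", X, y)
        assert np.allclose(p["a"], 0.0, atol=1e-9)
        assert p["b0"] == pytest.approx(6.0, abs=1e-9)

    def test_reciprocal_zero_predictor_rejected(self, rng):
        X = rng.uniform(1, 5, (20, 3))
        X[3, 1] = 0.0
        with pytest.raises(ValueError):
            fit_family_lsm("reciprocal", X, np.ones(20))

    def test_too_few_samples_rejected(self, rng):
        X = rng.uniform(1, 5, (3, 3))
        with pytest.raises(ValueError, match="samples"):
            fit_family_lsm("linear", X, np.ones(3))


class TestLsmNonlinearFamilies:
    def test_exponential_recovery_within_three_se(self):
        """Response-noise-only data recovers the generating coefficients."""
        spec = family_recovery_spec("exponential", seed=5, n=200, sigma_y=0.3)
        df = generate_samples(spec)
        res = fit_lsm(ModelSpec("exponential", "Lab", "MCC"), df, seed=5)
        eff_fit = effective_coefficients(res.model)
        eff_true = effective_coefficients(spec.model)
        # numerical-jacobian standard errors at the optimum
        from canopyn.fitting import _family_partials

        X = df[["mean_L", "mean_a", "mean_b"]].to_numpy()
        gs = df["gs_mcc"].to_numpy()
        params = {"a": np.asarray(res.model.a), "a0": res.model.a0,
                  "b0": res.model.b0, "b1": res.model.b1}
        _, J, _, _ = _family_partials("exponential", X, params, gs,
                                      np.asarray(res.model.normalizers))
        dof = len(df) - J.shape[1]
        s2 = res.objective / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov))
        # map to the effective scale (a_i / x'_i)
        scale = np.ones_like(se)
        scale[1:4] = 1.0 / np.asarray(res.model.normalizers)
        assert np.all(np.abs(eff_fit - eff_true) <= 3 * se * scale + 1e-9)

    @pytest.mark.parametrize("family", ["power", "logarithmic", "exponential"])
    def test_noiseless_interpolation(self, family):
        spec = family_recovery_spec(family, seed=2, n=60)
        df = generate_samples(spec)
        res = fit_lsm(ModelSpec(family, "Lab", "MCC"), df, seed=2)
        eff_fit = effective_coefficients(res.model)
        eff_true = effective_coefficients(spec.model)
        assert np.all(np.abs(eff_fit - eff_true) <= 1e-6 * np.maximum(np.abs(eff_true), 1.0))


class TestEiv:
    def test_error_free_predictors_degenerate_to_lsm(self, rng):
        X = rng.uniform(1, 5, (30, 3))
        y = 1.0 + X @ [1.5, -0.7, 0.3] + rng.normal(0, 0.4, 30)
        pl, *_ = fit_family_lsm("linear", X, y)
        pe, _, conv, _, adj = fit_family_eiv(
            "linear", X, y, sigma_x=[1e-12] * 3, sigma_y=0.4,
            cfg=EivConfig(n_starts=1),
        )
        assert conv
        assert np.allclose(pe["a"], pl["a"], atol=1e-8)
        assert pe["b0"] == pytest.approx(pl["b0"], abs=1e-8)
        assert np.abs(adj).max() == 0.0  # error-free columns carry no latents

    def test_straight_line_matches_deming(self):
        worst = 0.0
        for seed in range(50):
            r = np.random.default_rng(seed)
            xi = r.uniform(0, 10, 15)
            x = xi + r.normal(0, 0.5, 15)
            y = 1.0 + 2.0 * xi + r.normal(0, 0.5, 15)
            p, *_ = fit_family_eiv(
                "linear", x[:, None], y, sigma_x=[1.0], sigma_y=1.0,
                cfg=EivConfig(n_starts=1),
            )
            slope, intercept = deming_closed_form(x, y)
            worst = max(worst, abs(p["a"][0] - slope), abs(p["b0"] - intercept))
        assert worst < 1e-6

    def test_objective_never_worse_than_warm_start(self):
        spec = default_study_spec(n=48, seed=21)
        df = generate_samples(spec)
        mspec = ModelSpec("exponential", "Lab", "MCC")
        lsm = fit_lsm(mspec, df, seed=21)
        cfg = EivConfig(sigma_x=spec.sigma_x, sigma_y=spec.sigma_y, seed=21,
                        n_starts=1)
        res = fit_eiv(mspec, df, cfg)
        # at the warm start (latents = observations) the EIV objective is
        # the weighted LSM objective; optimization can only decrease it
        assert res.objective <= lsm.objective / spec.sigma_y ** 2 + 1e-9
        assert res.latent_adjustments is not None
        assert res.latent_adjustments.shape == (48, 4)

    def test_matches_scipy_odr_on_exponential(self):
        """Independent route: ODRPACK minimizes the same weighted
        orthogonal objective and must land on the same coefficients."""
        from scipy import odr

        rng = np.random.default_rng(7)
        n = 60
        xi = rng.uniform(10, 40, n)
        a0t, a1t, b0t, n1 = 8.0, -1.2, 2.0, 20.0
        y = b0t + a0t * np.exp(a1t * xi / n1) + rng.normal(0, 0.1, n)
        x = xi + rng.normal(0, 1.0, n)

        p, obj, conv, *_ = fit_family_eiv(
            "exponential", x[:, None], y, sigma_x=[1.0], sigma_y=0.1,
            normalizers=[n1], cfg=EivConfig(n_starts=2),
        )
        assert conv
        warm, *_ = fit_family_lsm("exponential", x[:, None], y, normalizers=[n1])
        out = odr.ODR(
            odr.RealData(x, y, sx=1.0, sy=0.1),
            odr.Model(lambda beta, xx: beta[2] + beta[0] * np.exp(beta[1] * xx / n1)),
            beta0=[warm["a0"], warm["a"][0], warm["b0"]],
        ).run()
        assert p["a0"] == pytest.approx(out.beta[0], rel=1e-4)
        assert p["a"][0] == pytest.approx(out.beta[1], rel=1e-4)
        assert p["b0"] == pytest.approx(out.beta[2], rel=1e-4)
        assert obj == pytest.approx(out.sum_square, rel=1e-8)

    def test_singular_response_variance_rejected(self, rng):
        X = rng.uniform(1, 5, (20, 1))
        with pytest.raises(ValueError):
            fit_family_eiv("linear", X, np.ones(20), sigma_x=[1.0], sigma_y=0.0)

    def test_reduces_attenuation_bias_on_noisy_predictors(self):
        """Classic errors-in-variables setting: LSM attenuates the slope,
        the EIV estimator recovers it (small Monte-Carlo pilot)."""
        true = default_study_model()
        eff_true = effective_coefficients(true)
        mspec = ModelSpec("exponential", "Lab", "MCC")
        E_l, E_e = [], []
        for rep in range(15):
            spec = default_study_spec(n=48, seed=3000 + rep)
            df = generate_samples(spec)
            rl = fit_lsm(mspec, df, seed=rep, n_starts=3)
            cfg = EivConfig(sigma_x=spec.sigma_x, sigma_y=spec.sigma_y,
                            seed=rep, n_starts=1)
            re = fit_eiv(mspec, df, cfg)
            E_l.append((effective_coefficients(rl.model) - eff_true) / np.abs(eff_true))
            E_e.append((effective_coefficients(re.model) - eff_true) / np.abs(eff_true))
        bias_l = np.abs(np.median(np.array(E_l), axis=0))
        bias_e = np.abs(np.median(np.array(E_e), axis=0))
        assert np.median(bias_e) < np.median(bias_l)


class TestEstimateSigma:
    def _samples(self, rng, n=20):
        spec = default_study_spec(n=n, seed=4)
        return generate_samples(spec)

    def test_three_percent_heuristic(self, rng):
        df = self._samples(rng)
        df["mean_L"] = 50.0 + 0 * df["mean_L"]
        df.loc[0, "mean_L"] = 50.0
        sigma_x, sigma_y = estimate_sigma(df, ModelSpec("linear", "Lab", "MCC"))
        assert sigma_x["mean_L"] == pytest.approx(1.5, rel=1e-6)
        assert sigma_y > 0

    def test_override_exact(self, rng):
        df = self._samples(rng)
        sigma_x, sigma_y = estimate_sigma(
            df, ModelSpec("linear", "Lab", "MCC"),
            override={"mean_L": 9.0, "total_N": 0.77},
        )
        assert sigma_x["mean_L"] == 9.0
        assert sigma_y == 0.77

    def test_perfect_fit_response_floored(self, rng):
        spec = default_study_spec(n=20, seed=8, sigma_y=0.0)
        spec.sigma_x = {k: 0.0 for k in spec.sigma_x}
        df = generate_samples(spec)
        df["total_N"] = 1.0 + 2.0 * df["mean_L"]  # exactly linear in L
        _, sigma_y = estimate_sigma(df, ModelSpec("linear", "Lab", "MCC"))
        assert sigma_y >= 1e-6

    def test_too_few_samples_rejected(self, rng):
        df = self._samples(rng, n=5)
        with pytest.raises(ValueError):
            estimate_sigma(df, ModelSpec("linear", "Lab", "MCC"))


class TestRecoveryAllFamilies:
    @pytest.mark.parametrize(
        "family", ["linear", "reciprocal", "power", "logarithmic", "exponential"]
    )
    def test_sign_recovery_at_low_noise(self, family):
        ok = 0
        n_reps = 10
        for seed in range(n_reps):
            spec = family_recovery_spec(family, seed=400 + seed, n=200,
                                        sigma_y=0.1, color_tolerance=0.01)
            df = generate_samples(spec)
            res = fit_lsm(ModelSpec(family, "Lab", "MCC"), df, seed=seed)
            et = effective_coefficients(spec.model)
            ef = effective_coefficients(res.model)
            if np.all(np.sign(et) == np.sign(ef)):
                ok += 1
        assert ok >= 0.9 * n_reps
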