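"""Conditional-least-squares estimation, stability metric and prediction."""
import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mwmar import (
    AbundancePanel,
    CovariatePanel,
    DegenerateFitError,
    InputError,
    MAR,
    MARParams,
    MaskSpec,
    fit_mar,
    predict_one_step,
    stability_lambda,
)
from mwmar.simulate import simulate_mar


def brute_force_cls(x, u, mask):
    """Independent oracle: numeric minimization of each equation's SSE."""
    T, p = x.shape
    q = 0 if u is None else u.shape[1]
    a = np.zeros(p)
    b = np.zeros((p, p))
    c = np.zeros((p, q))
    for i in range(p):
        bj = np.flatnonzero(mask.b_mask[i])
        ck = np.flatnonzero(mask.c_mask[i]) if q else np.array([], int)

        def sse(theta, i=i, bj=bj, ck=ck):
            ai = theta[0]
            bi = theta[1:1 + len(bj)]
            ci = theta[1 + len(bj):]
            pred = ai + x[:-1, bj] @ bi
            if len(ck):
                pred = pred + u[1:, ck] @ ci
            return float(np.sum((x[1:, i] - pred) ** 2))

        n_par = 1 + len(bj) + len(ck)
        res = optimize.minimize(sse, np.zeros(n_par), method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        a[i] = res.x[0]
        b[i, bj] = res.x[1:1 + len(bj)]
        if len(ck):
            c[i, ck] = res.x[1 + len(bj):]
    return a, b, c


class TestFitMar:
    def test_alternating_series_is_exact_ar1(self):
        panel = AbundancePanel([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        fit = fit_mar(panel)
        assert fit.params.a[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.params.b[0, 0] == pytest.approx(-1.0, abs=1e-10)
        assert fit.params.sigma2[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals.to_numpy(), 0.0, atol=1e-10)

    def test_residual_mean_zero_with_intercept(self, small_panel):
        fit = fit_mar(small_panel)
        means = np.nanmean(fit.residuals.to_numpy(), axis=0)
        assert np.allclose(means, 0.0, atol=1e-8)

    def test_recovers_generating_values(self):
        params = MARParams(a=[0.0, 0.0], b=[[0.5, 0.0], [0.0, 0.5]],
                           sigma2=[0.1, 0.1])
        panel = simulate_mar(params, T=500, seed=42)
        fit = fit_mar(panel)
        assert np.all(np.abs(fit.params.a - params.a) < 0.1)
        assert np.all(np.abs(fit.params.b - params.b) < 0.1)
        assert np.all(np.abs(fit.params.sigma2 - params.sigma2) < 0.1)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_small_instances(self, seed):
        """CLS equals numeric SSE minimization on tiny random instances."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 4))
        T = int(rng.integers(p + 4, 13))
        q = int(rng.integers(0, 3))
        x = rng.standard_normal((T, p))
        u = rng.standard_normal((T, q)) if q else None
        bm = rng.random((p, p)) < 0.7
        np.fill_diagonal(bm, True)
        cm = rng.random((p, q)) < 0.7 if q else None
        mask = MaskSpec(bm, cm)
        panel = AbundancePanel(x)
        cov = CovariatePanel(u) if q else None
        try:
            fit = fit_mar(panel, cov, mask)
        except (DegenerateFitError, InputError):
            return
        a, b, c = brute_force_cls(x, u, mask)
        assert np.allclose(fit.params.a, a, atol=1e-6)
        assert np.allclose(fit.params.b, b, atol=1e-6)
        if q:
            assert np.allclose(fit.params.c, c, atol=1e-6)

    def test_full_mask_matches_statsmodels_var(self, small_panel):
        """On a full mask with no covariates, CLS equals a VAR(1) OLS fit."""
        from statsmodels.tsa.api import VAR

        fit = fit_mar(small_panel)
        sm = VAR(small_panel.values).fit(maxlags=1, trend="c")
        assert np.allclose(fit.params.a, sm.params[0], atol=1e-8)
        # statsmodels stacks lag coefficients as params[1:p+1] per equation
        assert np.allclose(fit.params.b, sm.params[1:].T, atol=1e-8)

    def test_mask_honesty(self):
        """Excluded cells are exactly 0 and do not change included estimates."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 3))
        panel = AbundancePanel(x)
        bm = np.ones((3, 3), bool)
        bm[0, 2] = False
        fit = fit_mar(panel, mask=MaskSpec(bm))
        assert fit.params.b[0, 2] == 0.0
        # equation 0 must equal a 2-predictor regression done directly
        sub = np.column_stack([np.ones(39), x[:-1, 0], x[:-1, 1]])
        beta = np.linalg.lstsq(sub, x[1:, 0], rcond=None)[0]
        assert fit.params.a[0] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params.b[0, 0] == pytest.approx(beta[1], abs=1e-10)
        assert fit.params.b[0, 1] == pytest.approx(beta[2], abs=1e-10)

    def test_missing_rows_dropped_per_equation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((60, 2))
        x[10, 0] = np.nan  # hits eq 0 response at t=10 and both lags at t=11
        panel = AbundancePanel(x)
        fit = fit_mar(panel)
        # eq 0 loses rows 10 (response) and 11 (lag); eq 1 loses row 11 only
        assert fit.n_used[0] == 57
        assert fit.n_used[1] == 58
        assert np.isnan(fit.residuals.iloc[9, 0])  # response time index 10

    def test_rank_deficient_design_names_equation(self):
        x = np.column_stack([np.ones(20), np.random.default_rng(0).standard_normal(20)])
        panel = AbundancePanel(x, names=["const", "ok"])
        with pytest.raises(DegenerateFitError, match="const|ok"):
            fit_mar(panel)

    def test_too_short_series_rejected(self):
        panel = AbundancePanel(np.random.default_rng(0).standard_normal((4, 3)))
        with pytest.raises(InputError):
            fit_mar(panel)

    def test_misaligned_covariates_rejected(self, small_panel):
        u = CovariatePanel(np.random.default_rng(0).standard_normal((50, 1)))
        with pytest.raises(InputError):
            fit_mar(small_panel, u, MaskSpec.full(2, 1))

    def test_sigma_divisor_options(self, small_panel):
        f_n = fit_mar(small_panel, sigma_divisor="n")
        f_nk = fit_mar(small_panel, sigma_divisor="n-k")
        # k = 3 params per equation on a full 2-taxon mask
        n = f_n.n_used[0]
        assert f_nk.params.sigma2[0] == pytest.approx(
            f_n.params.sigma2[0] * n / (n - 3), rel=1e-12)

    def test_estimation_error_shrinks_with_series_length(self, stable_params_2):
        """Seed-averaged RMSE of B decreases over T in {100, 400, 1600}."""
        rmses = []
        for T in (100, 400, 1600):
            errs = []
            for seed in range(8):
                panel = simulate_mar(stable_params_2, T=T, seed=100 + seed)
                fit = fit_mar(panel)
                errs.append((fit.params.b - stable_params_2.b).ravel())
            rmses.append(float(np.sqrt(np.mean(np.concatenate(errs) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestStabilityLambda:
    @pytest.mark.parametrize("b, expected", [
        (np.zeros((3, 3)), 0.0),
        (np.diag([0.3, 0.9]), 0.9),
        ([[0.0, -0.8], [0.8, 0.0]], 0.8),  # complex pair +/- 0.8i
    ])
    def test_known_values(self, b, expected):
        assert stability_lambda(b) == pytest.approx(expected, abs=1e-10)

    def test_scaling_and_similarity_invariance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            b = rng.standard_normal((4, 4))
            lam = stability_lambda(b)
            c = float(rng.standard_normal()) * 2
            assert stability_lambda(c * b) == pytest.approx(abs(c) * lam, abs=1e-8)
            P = rng.standard_normal((4, 4)) + 4 * np.eye(4)
            sim = P @ b @ np.linalg.inv(P)
            assert stability_lambda(sim) == pytest.approx(lam, abs=1e-8)

    def test_non_square_rejected(self):
        with pytest.raises(InputError):
            stability_lambda(np.ones((2, 3)))


class TestPredictOneStep:
    def test_identity_dynamics(self):
        params = MARParams(a=np.zeros(3), b=np.eye(3))
        v = np.array([1.0, -2.0, 0.5])
        assert np.allclose(predict_one_step(params, v), v)

    def test_scalar_flip(self):
        params = MARParams(a=[1.0], b=[[-1.0]])
        assert predict_one_step(params, [0.0]) == pytest.approx([1.0])

    def test_alternating_fit_predicts_flip(self):
        panel = AbundancePanel([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        fit = fit_mar(panel)
        assert predict_one_step(fit.params, [1.0])[0] == pytest.approx(0.0, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        params = MARParams(a=np.zeros(2), b=np.eye(2))
        with pytest.raises(InputError):
            predict_one_step(params, [1.0, 2.0, 3.0])


class TestModelSurface:
    def test_model_results_roundtrip(self, small_panel):
        res = MAR(small_panel).fit()
        assert res.stability == stability_lambda(res.params.b)
        assert "MAR(1)" in res.summary()
        assert res.resid.shape == (119, 2)

    def test_from_dataframe(self, small_panel):
        frame = small_panel.frame.copy()
        frame["temp"] = np.sin(np.arange(len(frame)))
        frame["temp"] = (frame["temp"] - frame["temp"].mean()) / frame["temp"].std(ddof=1)
        model = MAR.from_dataframe(frame, taxa=["x", "y"], covariates=["temp"])
        res = model.fit()
        assert res.params.c.shape == (2, 1)
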