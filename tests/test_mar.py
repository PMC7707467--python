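"""Tests of the MAR(1) likelihood, fitters and information criterion."""

import numpy as np
import pytest
from scipy import stats

from marweb.mar import (
    MARParams,
    MARStructure,
    aicc,
    conditional_loglik,
    fit_ml,
    fit_ols,
    predict_one_step,
)
from marweb.synthetic import mar_scenario, simulate_anomalies


def _params(B, C=None, a=None, S=None):
    B = np.atleast_2d(B)
    p = B.shape[0]
    return MARParams(
        B=B,
        C=np.zeros((p, 0)) if C is None else C,
        a=np.zeros(p) if a is None else a,
        S=np.eye(p) if S is None else S,
    )


class TestConditionalLoglik:
    def test_standard_normal_zeros(self):
        p, n = 3, 9
        X = np.zeros((n + 1, p))
        ll = conditional_loglik(_params(np.zeros((p, p))), X)
        assert ll == pytest.approx(-(n * p / 2) * np.log(2 * np.pi))

    def test_matches_rowwise_density_oracle(self, rng):
        p, q, T = 2, 1, 6
        B = rng.normal(scale=0.3, size=(p, p))
        C = rng.normal(size=(p, q))
        a = rng.normal(size=p)
        A = rng.normal(size=(p, p))
        S = A @ A.T + 0.5 * np.eye(p)
        X = rng.normal(size=(T, p))
        U = rng.normal(size=(T, q))
        params = MARParams(B=B, C=C, a=a, S=S)
        expected = sum(
            stats.multivariate_normal.logpdf(
                X[t] - (B @ X[t - 1] + a + C @ U[t - 1]), mean=np.zeros(p), cov=S
            )
            for t in range(1, T)
        )
        assert conditional_loglik(params, X, U) == pytest.approx(expected, abs=1e-10)

    def test_singular_S_rejected_with_condition_number(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        params = _params(np.zeros((2, 2)), S=np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            conditional_loglik(params, X)

    def test_missing_transitions_dropped(self, rng):
        X = rng.normal(size=(10, 2))
        Xm = X.copy()
        Xm[4, 0] = np.nan  # kills transitions 3->4 and 4->5
        params = _params(0.2 * np.eye(2))
        keep = np.r_[X[1:4], X[6:]]
        prev = np.r_[X[0:3], X[5:9]]
        expected = sum(
            stats.multivariate_normal.logpdf(y - 0.2 * x, cov=np.eye(2))
            for y, x in zip(keep, prev)
        )
        assert conditional_loglik(params, Xm) == pytest.approx(expected, abs=1e-10)


class TestFitOls:
    def test_noiseless_identification(self):
        # S = 0: the data follow the deterministic recursion exactly, with a
        # persistently exciting covariate so the regressors stay full rank
        B = np.array([[0.5, -0.2], [0.1, 0.3]])
        C = np.array([[0.7], [-0.4]])
        a = np.array([0.1, -0.2])
        rng = np.random.default_rng(3)
        U = rng.normal(size=(40, 1))
        X = np.zeros((40, 2))
        X[0] = rng.normal(size=2)
        for t in range(1, 40):
            X[t] = B @ X[t - 1] + a + C @ U[t - 1]
        fit = fit_ols(X, U)
        assert np.allclose(fit.B, B, atol=1e-10)
        assert np.allclose(fit.C, C, atol=1e-10)
        assert np.allclose(fit.a, a, atol=1e-10)
        assert np.allclose(fit.S, 0.0, atol=1e-15)

    def test_scalar_ar1_slope_formula(self, rng):
        x = rng.normal(size=200)
        for t in range(1, 200):
            x[t] += 0.6 * x[t - 1]
        fit = fit_ols(x[:, None])
        y, z = x[1:], x[:-1]
        zc = z - z.mean()
        slope = np.sum(zc * (y - y.mean())) / np.sum(zc**2)
        assert fit.B[0, 0] == pytest.approx(slope, abs=1e-10)

    def test_residuals_orthogonal_to_regressors(self, small_fit_data):
        _, X, U = small_fit_data
        fit = fit_ols(X, U)
        Xa, Ua = X.to_numpy(), U.to_numpy()
        Z = np.hstack([Xa[:-1], Ua[:-1], np.ones((Xa.shape[0] - 1, 1))])
        R = Xa[1:] - Z @ np.hstack([fit.B, fit.C, fit.a[:, None]]).T
        assert np.max(np.abs(Z.T @ R)) < 1e-8

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))  # constant columns collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            fit_ols(X)


class TestFitMl:
    @pytest.mark.parametrize("s_form", ["diagonal", "unconstrained"])
    def test_masked_entries_exactly_zero(self, small_fit_data, s_form):
        _, X, U = small_fit_data
        structure = MARStructure(
            B_mask=np.eye(2, dtype=bool),
            C_mask=np.array([[True], [False]]),
            a_free=np.ones(2, dtype=bool),
            S_form=s_form,
        )
        fit = fit_ml(X, U, structure)
        assert fit.converged
        assert fit.params.B[0, 1] == 0.0 and fit.params.B[1, 0] == 0.0
        assert fit.params.C[1, 0] == 0.0

    def test_free_structure_matches_ols_oracle(self, small_fit_data):
        _, X, U = small_fit_data
        ols = fit_ols(X, U)
        ml = fit_ml(X, U, MARStructure.full(2, 1, "unconstrained"))
        assert np.max(np.abs(ml.params.B - ols.B)) < 1e-6
        assert np.max(np.abs(ml.params.C - ols.C)) < 1e-6
        assert np.max(np.abs(ml.params.a - ols.a)) < 1e-6
        assert np.max(np.abs(ml.params.S - ols.S)) < 1e-6

    def test_local_maximum_probe(self, small_fit_data):
        _, X, U = small_fit_data
        structure = MARStructure(
            B_mask=np.array([[True, True], [False, True]]),
            C_mask=np.array([[True], [True]]),
            a_free=np.ones(2, dtype=bool),
        )
        fit = fit_ml(X, U, structure)
        ll_opt = conditional_loglik(fit.params, X, U)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = fit.params
            dB = rng.normal(scale=1e-3, size=(2, 2)) * structure.B_mask
            dC = rng.normal(scale=1e-3, size=(2, 1)) * structure.C_mask
            probed = MARParams(B=pert.B + dB, C=pert.C + dC, a=pert.a, S=pert.S)
            assert conditional_loglik(probed, X, U) <= ll_opt + 1e-12

    def test_monotone_refitting(self, small_fit_data):
        """Freeing one extra parameter never decreases the optimum."""
        _, X, U = small_fit_data
        sparse = MARStructure(
            B_mask=np.eye(2, dtype=bool),
            C_mask=np.zeros((2, 1), dtype=bool),
            a_free=np.ones(2, dtype=bool),
        )
        richer = MARStructure(
            B_mask=np.array([[True, True], [False, True]]),
            C_mask=np.zeros((2, 1), dtype=bool),
            a_free=np.ones(2, dtype=bool),
        )
        assert (
            fit_ml(X, U, richer).loglik >= fit_ml(X, U, sparse).loglik - 1e-8
        )

    def test_taxon_order_invariance(self, small_fit_data):
        _, X, U = small_fit_data
        perm = [1, 0]
        fit = fit_ml(X, U, MARStructure.full(2, 1))
        fit_p = fit_ml(X.iloc[:, perm], U, MARStructure.full(2, 1))
        assert np.allclose(fit_p.params.B, fit.params.B[np.ix_(perm, perm)], atol=1e-8)
        assert np.allclose(fit_p.params.C, fit.params.C[perm], atol=1e-8)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_recovery_improves_with_sample_size(self):
        B = np.array([[0.5, -0.3], [0.2, 0.4]])
        S = 0.3 * np.eye(2)
        rmse = {}
        for n_years in (6, 48, 200):
            errs = []
            for seed in range(8):
                scenario = mar_scenario(B, S, n_years=n_years, seed=100 + seed)
                X, _ = simulate_anomalies(scenario)
                fit = fit_ml(X, None, MARStructure.full(2, 0))
                errs.append(np.mean((fit.params.B - B) ** 2))
            rmse[n_years] = float(np.sqrt(np.mean(errs)))
        assert rmse[48] < rmse[6] and rmse[200] < rmse[48]


class TestPredictOneStep:
    def test_identity_dynamics(self):
        params = _params(np.eye(2))
        x = np.array([0.3, -0.7])
        assert np.allclose(predict_one_step(params, x), x)

    def test_returns_intercept_at_origin(self):
        params = _params(np.zeros((2, 2)), a=np.array([1.5, -2.0]))
        assert np.allclose(predict_one_step(params, np.zeros(2)), [1.5, -2.0])

    def test_hand_worked_product(self):
        params = _params(np.array([[0.4, 0.0], [-0.2, 0.2]]))
        out = predict_one_step(params, np.array([1.0, 1.0]))
        assert out == pytest.approx([0.4, 0.0])


class TestAicc:
    def test_hand_worked_value(self):
        assert aicc(-100.0, 5, 50) == pytest.approx(200 + 10 + 60 / 44)

    def test_zero_parameters_reduces_to_deviance(self):
        assert aicc(-12.5, 0, 30) == pytest.approx(25.0)

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_exceeds_aic_for_positive_k(self, k):
        assert aicc(-50.0, k, 40) > -2 * -50.0 + 2 * k

    def test_undefined_for_small_samples(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(-10.0, 10, 11)


class TestSimulationClosedForms:
    def test_degenerate_process_stays_at_zero(self):
        scenario = mar_scenario(np.zeros((2, 2)), np.zeros((2, 2)), n_years=2, seed=1)
        X, _ = simulate_anomalies(scenario)
        assert np.allclose(X.to_numpy(), 0.0)

    def test_geometric_decay_without_noise(self):
        # x1 forced to (1, 1) via a for one step is awkward; instead check
        # the recursion directly: with S=0 and stationary start impossible
        # (mean 0), the half-life dynamics show up after an impulse.
        B = 0.5 * np.eye(2)
        params = MARParams(B=B, C=np.zeros((2, 0)), a=np.zeros(2), S=np.zeros((2, 2)))
        x = np.ones(2)
        for t in range(1, 6):
            x = predict_one_step(params, x)
            assert np.allclose(x, 0.5**t)
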