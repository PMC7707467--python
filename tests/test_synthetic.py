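"""Tests of the synthetic community generator against its closed forms."""

import numpy as np
import pandas as pd
import pytest

from marweb.mar import FitResult, MARParams, MARStructure
from marweb.preprocess import build_design_matrices
from marweb.synthetic import (
    INVADER_COVARIATES,
    ScenarioConfig,
    TaxonSpec,
    default_scenario,
    embed_in_abundance,
    invader_share,
    mar_scenario,
    recovery_metrics,
    simulate_anomalies,
    stationary_covariance,
)


class TestSimulateAnomalies:
    def test_degenerate_process_is_identically_zero(self):
        scenario = mar_scenario(np.zeros((3, 3)), np.zeros((3, 3)), n_years=3, seed=0)
        X, _ = simulate_anomalies(scenario)
        assert np.allclose(X.to_numpy(), 0.0)

    def test_determinism_bit_identical(self):
        scenario = default_scenario(seed=42, n_years=3)
        X1, U1 = simulate_anomalies(scenario)
        X2, U2 = simulate_anomalies(default_scenario(seed=42, n_years=3))
        pd.testing.assert_frame_equal(X1, X2)
        pd.testing.assert_frame_equal(U1, U2)

    def test_seed_changes_output(self):
        X1, _ = simulate_anomalies(default_scenario(seed=1, n_years=3))
        X2, _ = simulate_anomalies(default_scenario(seed=2, n_years=3))
        assert not np.allclose(X1, X2)

    def test_long_run_covariance_matches_lyapunov_fixed_point(self):
        B = np.array([[0.5, 0.2], [-0.2, 0.4]])
        B *= 0.6 / np.max(np.abs(np.linalg.eigvals(B)))
        S = np.eye(2)
        scenario = mar_scenario(B, S, n_years=1667, seed=5)  # T ~ 20k
        X, _ = simulate_anomalies(scenario)
        Xa = X.to_numpy()[:20_000]
        V = stationary_covariance(B, S)
        n_batches = 50
        blen = len(Xa) // n_batches
        covs = np.array([
            np.cov(Xa[i * blen:(i + 1) * blen].T, ddof=1) for i in range(n_batches)
        ])
        se = covs.std(axis=0, ddof=1) / np.sqrt(n_batches)
        assert np.all(np.abs(covs.mean(axis=0) - V) < 3 * se)

    def test_long_run_mean_matches_fixed_point(self):
        B = np.array([[0.4, 0.1], [0.0, 0.3]])
        a = np.array([0.5, -0.2])
        S = 0.5 * np.eye(2)
        scenario = mar_scenario(B, S, a=a, n_years=1000, seed=11)
        X, _ = simulate_anomalies(scenario)
        mu = np.linalg.solve(np.eye(2) - B, a)
        se = X.std(ddof=1).to_numpy() / np.sqrt(len(X) / 10)  # crude autocorr inflation
        assert np.all(np.abs(X.mean().to_numpy() - mu) < 3 * se)

    def test_unstable_spectral_radius_warns_but_runs(self):
        scenario = mar_scenario(1.05 * np.eye(2), 0.1 * np.eye(2), n_years=2, seed=0)
        with pytest.warns(RuntimeWarning, match="spectral radius"):
            X, _ = simulate_anomalies(scenario)
        assert np.all(np.isfinite(X.to_numpy()))

    def test_nonfinite_parameters_rejected_with_report(self):
        with pytest.raises(ValueError, match="true_B"):
            mar_scenario(np.full((2, 2), np.nan), np.eye(2))

    def test_asymmetric_S_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ScenarioConfig(
                n_years=2,
                taxa=[
                    TaxonSpec("a", "variate", np.zeros(12), np.ones(12)),
                    TaxonSpec("b", "variate", np.zeros(12), np.ones(12)),
                ],
                true_B=0.1 * np.eye(2),
                true_C=np.zeros((2, 0)),
                true_a=np.zeros(2),
                true_S=np.array([[1.0, 0.5], [0.2, 1.0]]),
            )


class TestEmbedInAbundance:
    def test_zero_anomalies_give_climatological_abundance(self):
        scenario = mar_scenario(np.zeros((2, 2)), np.zeros((2, 2)), n_years=2, seed=0)
        X, U = simulate_anomalies(scenario)
        series = embed_in_abundance(X, scenario, covariates=U)
        profile = np.expm1(scenario.taxa[0].log_mean)
        by_month = series.data["taxon_1"].groupby(series.data.index.month).mean()
        assert np.allclose(by_month.to_numpy(), profile, rtol=1e-12)

    def test_round_trip_recovers_anomalies(self):
        scenario = default_scenario(seed=9, n_years=12)
        X, U = simulate_anomalies(scenario)
        series = embed_in_abundance(X, scenario, covariates=U)
        design = build_design_matrices(series)
        scale = design.scale
        panel = pd.concat([X, U], axis=1)
        for spec in scenario.taxa:
            truth = panel[spec.name]
            month_means = truth.groupby(truth.index.month).transform("mean")
            z = design.X[spec.name] if spec.name in design.X else design.U[spec.name]
            rec = (z * scale.loc["sd", spec.name] + scale.loc["mean", spec.name])
            rec = rec / spec.log_sd[z.index.month - 1] + month_means
            assert float((rec - truth).abs().max()) < 1e-10

    def test_missing_months_masked(self):
        scenario = default_scenario(seed=0, n_years=3,
                                    missing_months=[("2006-03", "Ciliates")])
        X, U = simulate_anomalies(scenario)
        series = embed_in_abundance(X, scenario, covariates=U)
        assert series.missing.loc[pd.Period("2006-03", "M"), "Ciliates"]
        assert series.missing.to_numpy().sum() == 1

    def test_nonfinite_anomalies_rejected(self):
        scenario = mar_scenario(np.zeros((1, 1)), np.zeros((1, 1)), n_years=2, seed=0)
        X, _ = simulate_anomalies(scenario)
        X.iloc[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            embed_in_abundance(X, scenario)

    def test_overflowing_profile_reports_taxon(self):
        scenario = mar_scenario(np.zeros((1, 1)), np.zeros((1, 1)), n_years=2, seed=0)
        scenario.taxa[0].log_mean = np.full(12, 800.0)
        X, _ = simulate_anomalies(scenario)
        with pytest.raises(ValueError, match="taxon_1"):
            embed_in_abundance(X, scenario)


class TestInvaderShare:
    @staticmethod
    def _series(invader, native):
        scenario = default_scenario(seed=0, n_years=1)
        X, U = simulate_anomalies(scenario)
        series = embed_in_abundance(X, scenario, covariates=U)
        df = series.data.copy()
        df.loc[:, :] = 0.0
        df["P_forbesi_nauplii"] = invader
        df["Bosmina"] = native
        series.data = df
        return series

    def test_absent_invaders_give_zero(self):
        series = self._series(invader=0.0, native=10.0)
        share = invader_share(series, ["P_forbesi_nauplii"])
        assert np.allclose(share, 0.0)

    def test_pure_invader_month_gives_one(self):
        series = self._series(invader=5.0, native=0.0)
        share = invader_share(series, ["P_forbesi_nauplii"])
        assert np.allclose(share, 1.0)

    def test_hand_arithmetic(self):
        series = self._series(invader=90.0, native=10.0)
        share = invader_share(series, ["P_forbesi_nauplii"])
        assert np.allclose(share, 0.9)

    def test_microplankton_excluded_from_total(self):
        series = self._series(invader=90.0, native=10.0)
        series.data["Autotrophs"] = 1e6  # not zooplankton: must not dilute
        share = invader_share(series, ["P_forbesi_nauplii"])
        assert np.allclose(share, 0.9)

    def test_zero_total_undefined(self):
        series = self._series(invader=0.0, native=0.0)
        share = invader_share(series, ["P_forbesi_nauplii"])
        assert share.isna().all()

    def test_unknown_taxon_listed(self):
        series = self._series(invader=1.0, native=1.0)
        with pytest.raises(ValueError, match="Nessie"):
            invader_share(series, ["Nessie"])

    def test_default_scenario_invaders_dominate_peak_months(self):
        scenario = default_scenario(seed=4, n_years=12)
        X, U = simulate_anomalies(scenario)
        series = embed_in_abundance(X, scenario, covariates=U)
        share = invader_share(series, INVADER_COVARIATES)
        months = share.index.month
        assert float(np.median(share[(months == 8) | (months == 9)])) > 0.9


class TestRecoveryMetrics:
    @staticmethod
    def _fit_with(scenario, B, C, a):
        structure = MARStructure(
            B_mask=scenario.true_B != 0,
            C_mask=scenario.true_C != 0,
            a_free=np.ones(scenario.true_B.shape[0], dtype=bool),
        )
        params = MARParams(B=B, C=C, a=a, S=np.eye(scenario.true_B.shape[0]))
        return FitResult(
            params=params, structure=structure, loglik=0.0, n_transitions=10,
            k_free=structure.k_free, aicc=0.0,
            convergence={"converged": True},
        )

    def test_perfect_estimate_has_zero_error(self):
        scenario = default_scenario(seed=0, n_years=2)
        fit = self._fit_with(scenario, scenario.true_B, scenario.true_C, scenario.true_a)
        table = recovery_metrics(fit, scenario)
        assert np.allclose(table["bias"], 0.0)
        assert np.allclose(table["rmse"], 0.0)
        nonzero = table["truth"] != 0
        assert (table.loc[nonzero, "sign_accuracy"] == 1.0).all()

    def test_uniform_offset_shows_in_bias_and_rmse(self):
        scenario = default_scenario(seed=0, n_years=2)
        fit = self._fit_with(
            scenario,
            scenario.true_B + 0.1 * (scenario.true_B != 0),
            scenario.true_C + 0.1 * (scenario.true_C != 0),
            scenario.true_a + 0.1,
        )
        table = recovery_metrics(fit, scenario)
        assert np.allclose(table["bias"], 0.1)
        assert np.allclose(table["rmse"], 0.1)

    def test_dimension_mismatch_reported(self):
        scenario = default_scenario(seed=0, n_years=2)
        other = mar_scenario(np.eye(2) * 0.2, np.eye(2), n_years=2)
        fit = self._fit_with(scenario, scenario.true_B, scenario.true_C, scenario.true_a)
        with pytest.raises(ValueError, match="dimensions"):
            recovery_metrics(fit, other)
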