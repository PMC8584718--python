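import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import statsmodels.api as sm

from temppop import share_models as shm
from temppop import synthetic_data as sd
from temppop.data_model import Month, ValidationError, months_of_year, panel_index


def _panel(regions, months, values):
    return pd.Series(
        np.asarray(values), index=panel_index(regions["region_id"], months), name="nights"
    )


def _regions(rows):
    return pd.DataFrame(
        rows, columns=["region_id", "region_name", "climate_zone", "remoteness_class"]
    )


def poisson_mle_oracle(y, X, total):
    """Direct numerical maximisation of the offset Poisson log-likelihood.

    Independent of the IRLS route: minimises sum(mu) - sum(y log mu) with
    mu = total * exp(X beta) by quasi-Newton with an analytic gradient.
    """

    def negloglik(beta):
        mu = total * np.exp(X @ beta)
        return float(mu.sum() - y @ np.log(mu))

    def grad(beta):
        mu = total * np.exp(X @ beta)
        return X.T @ (mu - y)

    res = scipy.optimize.minimize(
        negloglik, np.zeros(X.shape[1]) - np.log(total) / X.shape[1],
        jac=grad, method="BFGS", options={"gtol": 1e-12, "maxiter": 2000},
    )
    return total * np.exp(X @ res.x)


class TestFitAirbnbShareModel:
    def test_uniform_counts_give_uniform_shares(self):
        regions = _regions([["A", "Alpha", "Warm humid summer", "Major Cities"]])
        months = months_of_year(2018)
        panel = _panel(regions, months, [40] * 12)
        fit = shm.fit_airbnb_share_model(panel, regions)
        assert fit.converged
        np.testing.assert_allclose(fit.shares.to_numpy(), 1 / 12, rtol=1e-8)

    def test_same_class_regions_pool_to_cell_means(self):
        # two regions with identical (climate, remoteness): the model is
        # saturated on class x month, so fitted cell means are class-month means
        regions = _regions(
            [
                ["A", "Alpha", "Warm humid summer", "Remote"],
                ["B", "Beta", "Warm humid summer", "Remote"],
            ]
        )
        months = months_of_year(2018)
        counts = np.full((2, 12), 6.0)
        counts[0, 0], counts[1, 0] = 10, 30
        panel = _panel(regions, months, counts.ravel())
        fit = shm.fit_airbnb_share_model(panel, regions)
        total = panel.sum()
        jan_cells = fit.shares.xs(1, level="month") * total
        np.testing.assert_allclose(jan_cells.to_numpy(), [20.0, 20.0], rtol=1e-6)

    def test_fitted_shares_sum_to_one(self, default_scenario):
        fit = shm.fit_airbnb_share_model(
            default_scenario.airbnb_panel, default_scenario.regions
        )
        assert abs(fit.shares.sum() - 1.0) <= 1e-9

    def test_rank_deficient_design_names_aliased_columns(self):
        # climate perfectly confounded with remoteness across regions
        regions = _regions(
            [
                ["A", "Alpha", "Hot humid summer", "Major Cities"],
                ["B", "Beta", "Warm humid summer", "Remote"],
            ]
        )
        months = months_of_year(2018)
        panel = _panel(regions, months, np.arange(1, 25))
        with pytest.raises(ValidationError, match="aliased"):
            shm.fit_airbnb_share_model(panel, regions)

    def test_zero_total_panel_rejected(self, toy_regions):
        months = months_of_year(2018)
        panel = _panel(toy_regions, months, [0] * 24)
        with pytest.raises(ValidationError, match="total"):
            shm.fit_airbnb_share_model(panel, toy_regions)


class TestFitOriginShareModel:
    def test_single_remoteness_collapses_to_month_model(self):
        # month-only model: fitted cell mean = month total / n_regions
        regions = _regions(
            [
                ["A", "Alpha", "Hot humid summer", "Inner Regional"],
                ["B", "Beta", "Warm humid summer", "Inner Regional"],
            ]
        )
        months = months_of_year(2018)
        rng = np.random.default_rng(7)
        counts = rng.integers(5, 50, size=(2, 12)).astype(float)
        panel = _panel(regions, months, counts.ravel())
        fit = shm.fit_origin_share_model(panel, regions)
        total = counts.sum()
        month_totals = counts.sum(axis=0)
        for r in range(2):
            cells = fit.shares.xs(regions["region_id"][r], level="region_id")
            np.testing.assert_allclose(
                cells.to_numpy(), month_totals / 2 / total, rtol=1e-6
            )

    def test_uniform_counts(self, toy_regions):
        months = months_of_year(2018)
        panel = _panel(toy_regions, months, [11] * 24)
        fit = shm.fit_origin_share_model(panel, toy_regions)
        np.testing.assert_allclose(fit.shares.to_numpy(), 1 / 24, rtol=1e-8)

    def test_constant_offset_equivalence(self, default_scenario):
        """Fitting without the offset and dividing by the total gives the
        same shares: a constant offset only shifts the intercept."""
        panel, regions = default_scenario.origin_panel, default_scenario.regions
        fit = shm.fit_origin_share_model(panel, regions)
        months = shm._panel_months(panel)
        X, _ = shm.build_design(regions, months, include_climate=False)
        res = sm.GLM(
            panel.reindex(X.index).to_numpy(dtype=float),
            X.to_numpy(),
            family=sm.families.Poisson(),
        ).fit(maxiter=100, tol=1e-10)
        shares_no_offset = np.asarray(res.fittedvalues) / panel.sum()
        assert np.abs(fit.shares.to_numpy() - shares_no_offset).max() <= 1e-10


class TestOracleAndCoding:
    def test_toy_panel_matches_numerical_ml_oracle(self, toy_regions):
        months = [Month(2018, m) for m in (1, 2, 3)]
        panel = _panel(toy_regions, months, [12.0, 5.0, 9.0, 20.0, 7.0, 31.0])
        fit = shm.fit_airbnb_share_model(panel, toy_regions)
        X, _ = shm.build_design(toy_regions, months, include_climate=True)
        mu_oracle = poisson_mle_oracle(
            panel.to_numpy(dtype=float), X.to_numpy(), float(panel.sum())
        )
        mu_fit = fit.shares.to_numpy() * fit.offset_total
        assert np.abs(mu_fit - mu_oracle).max() <= 1e-6

    def test_coding_invariance(self, toy_regions):
        """Fitted shares depend only on the design column space, not the
        coding: refitting on an invertible recombination of the columns
        reproduces them."""
        months = months_of_year(2018)
        rng = np.random.default_rng(3)
        panel = _panel(toy_regions, months, rng.integers(5, 80, size=24).astype(float))
        fit = shm.fit_airbnb_share_model(panel, toy_regions)
        X, _ = shm.build_design(toy_regions, months, include_climate=True)
        A = rng.normal(size=(X.shape[1], X.shape[1]))
        while abs(np.linalg.det(A)) < 1e-3:  # ensure invertibility
            A = rng.normal(size=(X.shape[1], X.shape[1]))
        res = sm.GLM(
            panel.reindex(X.index).to_numpy(),
            X.to_numpy() @ A,
            family=sm.families.Poisson(),
            offset=np.full(len(panel), np.log(panel.sum())),
        ).fit(maxiter=200, tol=1e-12)
        shares_recoded = np.asarray(res.fittedvalues) / panel.sum()
        assert np.abs(fit.shares.to_numpy() - shares_recoded).max() <= 1e-10


class TestPredictShares:
    def test_fitting_set_prediction_has_unit_factor(self, default_scenario):
        sc = default_scenario
        fit = shm.fit_airbnb_share_model(sc.airbnb_panel, sc.regions)
        surface = shm.predict_shares(fit, sc.regions, sc.config.months)
        assert surface.renormalization_factor == pytest.approx(1.0, abs=1e-9)
        pd.testing.assert_series_equal(
            surface.shares, fit.shares, check_exact=False, rtol=1e-9
        )

    def test_subset_prediction_renormalises(self, default_scenario):
        sc = default_scenario
        fit = shm.fit_airbnb_share_model(sc.airbnb_panel, sc.regions)
        surface = shm.predict_shares(fit, sc.regions.iloc[:10], sc.config.months)
        assert surface.renormalization_factor > 1.0
        assert surface.shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unseen_level_is_an_error(self, default_scenario):
        sc = default_scenario
        fit = shm.fit_airbnb_share_model(sc.airbnb_panel, sc.regions)
        unseen = sc.regions.iloc[:2].copy()
        unseen.loc[unseen.index[0], "climate_zone"] = "Hot dry summer, cold winter"
        with pytest.raises(ValidationError, match="not seen at fit time"):
            shm.predict_shares(fit, unseen, sc.config.months)

    def test_empty_months_is_an_error(self, default_scenario):
        sc = default_scenario
        fit = shm.fit_airbnb_share_model(sc.airbnb_panel, sc.regions)
        with pytest.raises(ValidationError, match="empty"):
            shm.predict_shares(fit, sc.regions, [])


class TestParameterRecovery:
    def test_recovers_true_surfaces_at_large_totals(self, default_scenario):
        sc = default_scenario
        lam_fit = shm.fit_airbnb_share_model(sc.airbnb_panel, sc.regions)
        lam = shm.predict_shares(lam_fit, sc.regions, sc.config.months)
        assert np.abs(lam.shares - sc.truth.lambda_true.shares).max() <= 5e-4
        eta_fit = shm.fit_origin_share_model(sc.origin_panel, sc.regions)
        eta = shm.predict_shares(eta_fit, sc.regions, sc.config.months)
        assert np.abs(eta.shares - sc.truth.eta_true.shares).max() <= 5e-4

    def test_recovery_error_shrinks_with_information(self):
        """Mean max-abs share error is non-increasing as the panel total
        grows from 1e4 to 1e6 nights."""
        cfg = sd.ScenarioConfig(seed=11, n_regions=12)
        regions = sd.generate_regions(cfg)
        coeffs = sd.default_coefficients(
            climates=sorted(set(regions["climate_zone"])),
            remoteness=sorted(set(regions["remoteness_class"])),
        )
        truth = sd.true_share_surface(regions, cfg.months, coeffs)
        errors = []
        for total in (10_000, 100_000, 1_000_000):
            errs = []
            for seed in (101, 102, 103):
                panel = sd.simulate_count_panel(truth, total, seed)
                fit = shm.fit_airbnb_share_model(panel, regions)
                errs.append(float(np.abs(fit.shares - truth.shares).max()))
            errors.append(np.mean(errs))
        assert errors[0] >= errors[1] >= errors[2]
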