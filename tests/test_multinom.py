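"""Multinomial logit MLE, Wald intervals, and the two survey model builders."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import coatmorph as cm
from coatmorph.multinom import ABSENCE, DesignMatrix, RankError


def _simulate_multinomial(rng, n, P, K, scale=0.8):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, P - 1))])
    B = rng.normal(scale=scale, size=(K - 1, P))
    eta = np.concatenate([np.zeros((n, 1)), X @ B.T], axis=1)
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(K, p=pi) for pi in p]).astype(str)
    return X, y, B


class TestFit:
    def test_binary_reduction_matches_logistic_mle(self):
        """K=2 multinomial is binary logistic regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X, y, _ = _simulate_multinomial(rng, 400, 3, 2)
        fit = cm.fit_multinomial(X, y, reference="0")
        logit = sm.Logit((y == "1").astype(int), X).fit(disp=0)
        assert np.allclose(fit.coef[0], logit.params, atol=1e-6)

    def test_saturated_two_by_two_cross_ratio(self):
        """One binary covariate, cells x=0:{A:10,B:10}, x=1:{A:5,B:20};
        the fitted OR equals the closed-form cross ratio (20/5)/(10/10) = 4."""
        x = np.repeat([0, 0, 1, 1], [10, 10, 5, 20])
        y = np.repeat(["A", "B", "A", "B"], [10, 10, 5, 20])
        X = np.column_stack([np.ones(len(x)), x])
        fit = cm.fit_multinomial(X, y, reference="A")
        assert np.exp(fit.coef[0, 1]) == pytest.approx(4.0, rel=1e-6)

    def test_saturated_model_reproduces_cell_proportions(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 300)
        y = np.where(rng.random(300) < 0.2 + 0.4 * x, "B", "A")
        X = np.column_stack([np.ones(300), x])
        fit = cm.fit_multinomial(X, y, reference="A")
        p = cm.predict_proba(fit, X)[:, 1]
        for cell in (0, 1):
            emp = (y[x == cell] == "B").mean()
            assert p[x == cell][0] == pytest.approx(emp, abs=1e-8)

    def test_probabilities_sum_to_one_and_score_vanishes(self):
        rng = np.random.default_rng(2)
        X, y, _ = _simulate_multinomial(rng, 500, 4, 4)
        fit = cm.fit_multinomial(X, y, reference="0")
        assert fit.converged
        p = cm.predict_proba(fit, X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.abs(cm.score_vector(fit, X, y)).max() < 1e-6 * len(y)

    def test_oracle_equivalence_small_batch(self):
        """Independent reference implementation agrees to 4 decimals."""
        from statsmodels.api import MNLogit

        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(80, 200))
            P = int(rng.integers(2, 5))
            K = int(rng.integers(2, 5))
            X, y, _ = _simulate_multinomial(rng, n, P, K)
            if len(set(y)) < K:
                continue
            fit = cm.fit_multinomial(X, y, reference="0")
            oracle = MNLogit(y.astype(int), X).fit(disp=0, method="newton")
            assert np.abs(fit.coef - np.asarray(oracle.params).T).max() < 1e-4
            assert np.abs(fit.se - np.asarray(oracle.bse).T).max() < 1e-4

    def test_degenerate_constant_reference_diverges_without_ridge(self):
        X = np.column_stack([np.ones(50), np.linspace(-1, 1, 50)])
        y = np.array(["ref"] * 50)
        with pytest.warns(UserWarning):
            fit = cm.fit_multinomial(X, y, reference="ref", categories=("ref", "other"))
        assert not fit.converged

    def test_ridge_stabilises_degenerate_fit(self):
        X = np.column_stack([np.ones(50), np.linspace(-1, 1, 50)])
        y = np.array(["ref"] * 50)
        fit = cm.fit_multinomial(X, y, reference="ref", categories=("ref", "other"), ridge=1e-2)
        assert np.isfinite(fit.coef).all()
        assert np.abs(fit.coef).max() < 40

    def test_rank_deficiency_names_columns(self):
        n = 60
        x = np.linspace(0, 1, n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = np.where(x > 0.5, "A", "B")
        with pytest.raises(RankError, match=r"x[12]"):
            cm.fit_multinomial(X, y, reference="A")


class TestWald:
    def test_zero_coefficient_symmetric_about_one(self):
        fit = _toy_fit(b=0.0, s=0.3)
        row = cm.wald_intervals(fit, 0.95).iloc[1]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["lower"] * row["upper"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_vanishing_se_collapses_interval(self):
        fit = _toy_fit(b=np.log(2), s=1e-12)
        row = cm.wald_intervals(fit, 0.975).iloc[1]
        assert row["lower"] == pytest.approx(2.0) and row["upper"] == pytest.approx(2.0)

    def test_normal_quantile_arithmetic(self):
        """b=1, s=0.5 at 95%: bounds are exp(1 +/- 1.96 * 0.5)."""
        fit = _toy_fit(b=1.0, s=0.5)
        row = cm.wald_intervals(fit, 0.95).iloc[1]
        z = norm.ppf(0.975)
        assert row["lower"] == pytest.approx(np.exp(1 - z * 0.5))
        assert row["upper"] == pytest.approx(np.exp(1 + z * 0.5))
        assert row["lower"] == pytest.approx(np.exp(1 - 1.96 * 0.5), rel=1e-3)

    def test_two_sided_97p5_level_quantile(self):
        fit = _toy_fit(b=0.5, s=0.2)
        row = cm.wald_intervals(fit, 0.975).iloc[1]
        z = norm.ppf(0.5 + 0.975 / 2)  # ~2.2414
        assert row["upper"] == pytest.approx(np.exp(0.5 + z * 0.2))

    def test_level_bounds_enforced(self):
        fit = _toy_fit(0.1, 0.1)
        for bad in (0.4, 1.0, 1.2):
            with pytest.raises(ValueError):
                cm.wald_intervals(fit, bad)


def _toy_fit(b: float, s: float) -> cm.MultinomFit:
    cov = np.diag([1e-8, s**2])
    return cm.MultinomFit(
        reference="A",
        categories=("A", "B"),
        names=("intercept", "x"),
        coef=np.array([[0.0, b]]),
        cov=cov,
        loglik=0.0,
        iterations=1,
        converged=True,
    )


class TestBuilders:
    def _covariates(self, n=5, veg=None):
        rng = np.random.default_rng(3)
        return pd.DataFrame(
            {
                "site_id": [f"S{i}" for i in range(n)],
                "elevation": rng.uniform(0, 1500, n),
                "roughness": rng.uniform(0, 100, n),
                "isothermality": rng.normal(50, 5, n),
                "fpar": rng.uniform(0.1, 0.9, n),
                "dtnt": rng.uniform(1, 60, n),
                "vegetation": veg or ["grassland", "woodland", "forest", "woodland", "grassland"],
            }
        )

    def _summaries(self, modal):
        return pd.DataFrame({"site_id": [f"S{i}" for i in range(len(modal))], "modal_category": modal})

    def test_spatial_shape_and_encoding(self):
        X, y = cm.build_spatial_model(
            self._summaries(["solid_black", "orange", "mackerel_brown", "solid_black", "tortoiseshell"]),
            self._covariates(),
        )
        assert X.X.shape == (5, 8)  # intercept + 5 continuous + 2 veg dummies
        assert X.names[0] == "intercept" and X.kinds[0] == "intercept"
        assert sum(k == "dummy" for k in X.kinds) == 2
        assert set(X.standardization) == {"elevation", "roughness", "isothermality", "fpar", "dtnt"}
        assert len(y) == 5

    def test_excluded_modal_sites_dropped(self):
        X, y = cm.build_spatial_model(
            self._summaries(["solid_black", "excluded", "orange", "solid_black", "orange"]),
            self._covariates(),
        )
        assert len(y) == 4 and "excluded" not in set(y)

    def test_missing_covariates_listed(self):
        cov = self._covariates()
        cov.loc[2, "fpar"] = np.nan
        with pytest.raises(ValueError, match="S2"):
            cm.build_spatial_model(self._summaries(["solid_black"] * 5), cov)

    def test_constant_column_raises_rank_error(self):
        cov = self._covariates()
        cov["dtnt"] = 7.0
        with pytest.raises(RankError, match="dtnt"):
            cm.build_spatial_model(self._summaries(["solid_black"] * 5), cov)

    def _nights(self):
        return pd.DataFrame(
            {
                "site_id": ["A"] * 8 + ["B"] * 8,
                "date": list(pd.date_range("2019-01-01", periods=8)) * 2,
                "moon_class": ["full", "full", "new", "new", "full", "new", "full", "new"] * 2,
            }
        )

    def _weather(self):
        dates = pd.date_range("2019-01-01", periods=8)
        return pd.DataFrame(
            {
                "date": dates,
                "rainfall": [0, 1, 2, 0, 4, 0.5, 3, 1.5],
                "solar_exposure": [10, 12, 14, 9, 11, 16, 8, 13],
                "min_temp": [5, 6, 7, 8, 4, 9, 3, 6.5],
            }
        )

    def test_temporal_absence_rows_and_reference(self):
        daily = pd.DataFrame(
            {
                "site_id": ["A", "B"],
                "date": [pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-03")],
                "category": ["mackerel_brown", "orange"],
            }
        )
        X, y = cm.build_temporal_model(daily, self._nights(), self._weather())
        assert len(y) == 16  # 14 absences + 2 category rows
        assert (y == ABSENCE).sum() == 14

    def test_multi_category_night_suppresses_absence(self):
        daily = pd.DataFrame(
            {
                "site_id": ["A", "A"],
                "date": [pd.Timestamp("2019-01-01")] * 2,
                "category": ["mackerel_brown", "solid_black"],
            }
        )
        X, y = cm.build_temporal_model(daily, self._nights(), self._weather())
        assert len(y) == 17  # 15 absences + 2 category rows on the shared night
        assert sorted(set(y) - {ABSENCE}) == ["mackerel_brown", "solid_black"]

    def test_moon_coding_and_interaction_column(self):
        X, y = cm.build_temporal_model(
            pd.DataFrame(columns=["site_id", "date", "category"]),
            self._nights(),
            self._weather(),
            cm.ModelConfig(standardize=False),
        )
        moon = X.X[:, X.names.index("moon[new]")]
        solar = X.X[:, X.names.index("solar_exposure")]
        inter = X.X[:, X.names.index("moon[new]:solar_exposure")]
        assert set(moon) == {0.0, 1.0}
        assert np.allclose(inter, moon * solar)
        # full-moon night: interaction is 0 * solar
        assert np.all(inter[moon == 0] == 0)

    def test_excluded_night_in_input_rejected(self):
        nights = self._nights()
        nights.loc[0, "moon_class"] = "excluded"
        with pytest.raises(ValueError, match="excluded"):
            cm.build_temporal_model(
                pd.DataFrame(columns=["site_id", "date", "category"]), nights, self._weather()
            )


def test_coverage_of_wald_intervals_on_simulated_data():
    """95% intervals cover the generating coefficients at ~nominal rate."""
    rng = np.random.default_rng(42)
    z = norm.ppf(0.975)
    covered = total = 0
    for _ in range(40):
        X, y, B = _simulate_multinomial(rng, 600, 3, 3, scale=0.5)
        fit = cm.fit_multinomial(X, y, reference="0")
        lo, hi = fit.coef - z * fit.se, fit.coef + z * fit.se
        covered += int(((B >= lo) & (B <= hi)).sum())
        total += B.size
    assert covered / total > 0.90
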