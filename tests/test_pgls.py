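"""PGLS regression: OLS reduction, likelihood oracle, model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from breedsync.pgls import (
    CANDIDATE_FORMULAS,
    design_matrix,
    fit_formula,
    model_comparison,
    ols_fit,
    parse_formula,
    pearson,
    pgls_fit,
    prediction_surface,
)
from breedsync.phylo import lambda_transform, phylo_covariance
from breedsync.synthetic import TraitGenConfig, generate_yule_tree, simulated_study


class TestFormulas:
    def test_star_expands_to_mains_plus_interaction(self):
        spec = parse_formula("Contingency * Constancy + Gregariousness")
        assert spec.mains == ["Contingency", "Constancy", "Gregariousness"]
        assert spec.interactions == [("Contingency", "Constancy")]

    def test_all_candidate_formulas_parse(self):
        for f in CANDIDATE_FORMULAS:
            parse_formula(f)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            parse_formula("Contingency + Bodymass")


class TestDesignMatrix:
    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(0)
        n = 12
        return pd.DataFrame(
            {
                "contingency": rng.uniform(0, 0.5, n),
                "constancy": rng.uniform(0, 1, n),
                "latitude": rng.uniform(-60, 60, n),
                "diet": ["browser", "grazer", "mixed"] * 4,
                "calf_behaviour": ["follower", "hider"] * 6,
                "gregariousness": rng.integers(1, 6, n),
            }
        )

    def test_interaction_column_is_product(self, data):
        X, labels = design_matrix(data, parse_formula("Contingency * Constancy"))
        assert labels == ["Intercept", "Contingency", "Constancy",
                          "Contingency:Constancy"]
        assert np.allclose(X[:, 3], X[:, 1] * X[:, 2])

    def test_diet_treatment_coding_two_indicators(self, data):
        X, labels = design_matrix(data, parse_formula("Diet"))
        assert labels == ["Intercept", "Diet[grazer]", "Diet[mixed]"]
        # browser rows are all-zero in the indicator block
        browser_rows = data["diet"] == "browser"
        assert np.all(X[browser_rows.to_numpy(), 1:] == 0)

    def test_latitude_entered_as_absolute(self, data):
        X, _ = design_matrix(data, parse_formula("Latitude"))
        assert np.allclose(X[:, 1], np.abs(data["latitude"]))

    def test_categorical_interaction_expands_per_level(self, data):
        X, labels = design_matrix(data, parse_formula("Latitude + Constancy * Diet"))
        assert "Constancy:Diet[grazer]" in labels
        assert "Constancy:Diet[mixed]" in labels

    def test_unseen_level_rejected(self, data):
        bad = data.assign(diet=["carnivore"] * len(data))
        with pytest.raises(ValueError, match="unseen level"):
            design_matrix(bad, parse_formula("Diet"))


class TestPglsFit:
    def test_identity_covariance_reduces_to_ols(self):
        # 50 random problems checked against statsmodels OLS to 1e-8.
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, p = rng.integers(15, 40), rng.integers(2, 5)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            y = rng.standard_normal(n)
            fit = pgls_fit(X, y, np.eye(n), estimate_lambda=False)
            ols = sm.OLS(y, X).fit()
            assert np.allclose(fit.coef["estimate"], ols.params, atol=1e-8)
            assert np.allclose(fit.coef["se"], ols.bse, atol=1e-8)
            assert np.allclose(fit.coef["t"], ols.tvalues, atol=1e-8)
            assert np.allclose(fit.coef["p"], ols.pvalues, atol=1e-8)

    def test_noiseless_data_recovers_exact_coefficients(self):
        rng = np.random.default_rng(1)
        n = 20
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        b = np.array([1.0, -2.0, 0.5])
        fit = pgls_fit(X, X @ b, np.eye(n), estimate_lambda=False)
        assert np.allclose(fit.coef["estimate"], b, atol=1e-8)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-16)

    def test_loglik_matches_direct_mvn_oracle_small_tree(self):
        # n <= 10 tips: profile likelihood vs explicit-inverse MVN density.
        tree = generate_yule_tree(5, seed=11)
        V = phylo_covariance(tree).V
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(5), rng.standard_normal(5)])
        y = rng.standard_normal(5) + 2.0
        for lam in (0.0, 0.3, 1.0):
            fit = pgls_fit(X, y, V, estimate_lambda=False, fixed_lambda=lam)
            Vl = fit.sigma2_hat * lambda_transform(V, lam)
            mean = X @ fit.coef["estimate"].to_numpy()
            oracle = stats.multivariate_normal(mean=mean, cov=Vl).logpdf(y)
            assert fit.logLik == pytest.approx(oracle, abs=1e-8)

    def test_aicc_approaches_aic_for_large_n(self):
        rng = np.random.default_rng(3)
        diffs = []
        for n in (30, 300, 3000):
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            fit = pgls_fit(X, y, np.eye(n), estimate_lambda=False)
            diffs.append(fit.AICc - fit.AIC)
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < 0.01

    def test_collinear_design_rejected(self):
        n = 20
        x = np.linspace(0, 1, n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="singular design"):
            pgls_fit(X, np.random.default_rng(0).standard_normal(n), np.eye(n),
                     estimate_lambda=False)

    def test_small_n_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="too small"):
            pgls_fit(X, np.zeros(4), np.eye(4), estimate_lambda=False)


class TestModelComparison:
    def test_duplicate_spec_identical_aicc(self):
        _, traits, V = simulated_study(n_species=20, seed=2)
        table, _ = model_comparison(
            traits, V, formulas=("Contingency", "Contingency"))
        assert len(table) == 2
        assert table["AICc"].iloc[0] == pytest.approx(table["AICc"].iloc[1])

    def test_inestimable_specs_skipped(self):
        # Simulated table lacks life-history columns: those formulas drop out.
        _, traits, V = simulated_study(n_species=20, seed=3)
        table, _ = model_comparison(traits, V)
        assert "Diet" not in " ".join(table["formula"])
        assert "Contingency * Constancy" in set(table["formula"])

    def test_pure_noise_covariate_usually_penalized(self):
        # ΔAICc > 0 for truth + noise in most replicates.
        worse = 0
        reps = 40
        for seed in range(reps):
            _, traits, V = simulated_study(
                n_species=20, seed=seed,
                trait_config=TraitGenConfig(seed=7000 + seed),
                include_life_history=True,
            )
            table, _ = model_comparison(
                traits, V,
                formulas=("Contingency * Constancy",
                          "Contingency * Constancy + Gregariousness"))
            sub = table.set_index("formula")["AICc"]
            if (sub["Contingency * Constancy + Gregariousness"]
                    > sub["Contingency * Constancy"]):
                worse += 1
        assert worse > reps / 2


class TestPredictionSurface:
    def test_grid_covers_stated_ranges(self):
        _, traits, V = simulated_study(n_species=20, seed=4)
        fit = fit_formula(traits, "Contingency * Constancy", V)
        grid = prediction_surface(fit, n_grid=11)
        assert grid["contingency"].min() == 0.0
        assert grid["contingency"].max() == 0.5
        assert grid["constancy"].max() == 1.0
        b = dict(zip(fit.coef["term"], fit.coef["estimate"]))
        row = grid.iloc[60]
        expect = (b["Intercept"] + b["Contingency"] * row.contingency
                  + b["Constancy"] * row.constancy
                  + b["Contingency:Constancy"] * row.contingency * row.constancy)
        assert row.predicted_log_birth_season_length == pytest.approx(expect)


class TestOlsAndPearson:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = ols_fit(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_pearson_self_correlation(self):
        x = np.random.default_rng(0).standard_normal(30)
        r, t, p = pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            ols_fit(np.ones(10), np.arange(10.0))

    def test_independent_data_slope_within_3_se(self):
        rng = np.random.default_rng(9)
        covered = 0
        for _ in range(200):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40)
            res = ols_fit(x, y)
            covered += abs(res.slope) <= 3 * res.se
        assert covered >= 0.99 * 200 - 3  # 3-SE coverage ~99.7%
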