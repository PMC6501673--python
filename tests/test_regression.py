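import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, special

from collide.data_model import SpeciesTraits
from collide.phylo import parse_newick, correlation_matrix
from collide.regression import (
    LOGISTIC_FORMULAS,
    PhyloGLMFit,
    build_design,
    compare_models,
    fit_phylo_logistic,
    fit_phylo_poisson,
    simulate_liability_outcome,
    _eig_correlation,
)


def firth_logistic_oracle(X, y):
    """Independent penalized-logistic oracle: direct maximization of the
    Jeffreys-penalized log-likelihood."""

    def negpll(beta):
        eta = X @ beta
        mu = special.expit(eta)
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        W = mu * (1 - mu)
        sign, logdet = np.linalg.slogdet(X.T @ (W[:, None] * X))
        return -(ll + 0.5 * logdet)

    res = optimize.minimize(negpll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x


@pytest.fixture
def traits_design():
    return [
        SpeciesTraits("a", "yes", "forest", "upper", 1e6),
        SpeciesTraits("b", "no", "edge", "lower", 2e6),
        SpeciesTraits("c", "yes", "open", "lower", 5e5),
        SpeciesTraits("d", "no", "open", "upper", 3e6),
    ]


class TestBuildDesign:
    def test_flight_call_only_two_species(self, traits_design):
        X, names, sp = build_design(traits_design[:2], "flight_call")
        assert names == ["intercept", "flight_call[yes]"]
        np.testing.assert_allclose(X, [[1, 1], [1, 0]])

    def test_habitat_gets_two_indicators(self, traits_design):
        X, names, _ = build_design(traits_design, "habitat")
        assert names == ["intercept", "habitat[forest]", "habitat[open]"]
        np.testing.assert_allclose(X[:, 1], [1, 0, 0, 0])
        np.testing.assert_allclose(X[:, 2], [0, 0, 1, 1])

    def test_full_formula_has_six_columns(self, traits_design):
        X, names, _ = build_design(traits_design, LOGISTIC_FORMULAS[3])
        assert X.shape[1] == 6
        assert names[-1] == "log_pop_size"
        # standardized log population size
        assert X[:, -1].mean() == pytest.approx(0, abs=1e-12)
        assert X[:, -1].std() == pytest.approx(1, abs=1e-12)

    def test_species_subset_and_order(self, traits_design):
        X, _, sp = build_design(traits_design, "flight_call", species=["d", "a"])
        assert sp == ["d", "a"]
        np.testing.assert_allclose(X[:, 1], [0, 1])

    def test_unknown_term_and_missing_species(self, traits_design):
        with pytest.raises(ValueError, match="unknown formula"):
            build_design(traits_design, "flight_call + wingspan")
        with pytest.raises(ValueError, match="without trait rows"):
            build_design(traits_design, "flight_call", species=["zzz"])

    def test_unseen_level_rejected(self):
        frame = pd.DataFrame(
            {"flight_call": ["yes", "sometimes"], "habitat": ["edge", "edge"],
             "stratum": ["lower", "lower"], "regional_pop_size": [1.0, 2.0]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="unseen"):
            build_design(frame, "flight_call")

    def test_ebird_tally_requires_values(self, traits_design):
        with pytest.raises(ValueError, match="ebird_tally"):
            build_design(traits_design, "ebird_tally + flight_call")


class TestPhyloLogistic:
    def test_star_tree_matches_firth_oracle(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n), rng.standard_normal(n)])
        y = rng.binomial(1, special.expit(X @ np.array([-0.5, 1.5, 0.7]))).astype(float)
        C = np.eye(n)
        fit = fit_phylo_logistic(y, X, C, n_boot=0, lam_fixed=0.0)
        oracle = firth_logistic_oracle(X, y)
        got = np.array(list(fit.coef.values()))
        np.testing.assert_allclose(got, oracle, atol=1e-3)

    def test_constant_outcome_flags_separation_with_finite_fit(self, corr150):
        n = len(corr150.species)
        X = np.column_stack([np.ones(n), np.zeros(n)])
        X[: n // 2, 1] = 1
        y = np.ones(n)
        fit = fit_phylo_logistic(y, X, corr150, n_boot=10, rng=0)
        assert fit.separation
        assert all(np.isfinite(v) for v in fit.coef.values())
        lo, hi = fit.bootstrap_ci["b1"]
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_bootstrap_deterministic_under_seed(self, corr150, rng):
        n = len(corr150.species)
        evals, Q = _eig_correlation(corr150)
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n)])
        y = simulate_liability_outcome(X, np.array([-0.5, 2.0]), evals, Q, 0.5, rng)
        f1 = fit_phylo_logistic(y, X, corr150, n_boot=25, rng=7)
        f2 = fit_phylo_logistic(y, X, corr150, n_boot=25, rng=7)
        assert f1.bootstrap_ci == f2.bootstrap_ci
        f3 = fit_phylo_logistic(y, X, corr150, n_boot=25, rng=8)
        assert f1.bootstrap_ci != f3.bootstrap_ci

    def test_marginal_probabilities_of_simulator(self, corr150, rng):
        # liability simulator must have expit(X beta) marginals for any lambda
        evals, Q = _eig_correlation(corr150)
        n = len(corr150.species)
        X = np.column_stack([np.ones(n)])
        beta = np.array([0.8])
        draws = np.mean(
            [
                simulate_liability_outcome(X, beta, evals, Q, 0.7, rng).mean()
                for _ in range(400)
            ]
        )
        assert draws == pytest.approx(special.expit(0.8), abs=0.02)

    def test_sign_recovery_strong_positive_effect(self, corr150, rng):
        evals, Q = _eig_correlation(corr150)
        n = len(corr150.species)
        x = rng.binomial(1, 0.5, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        beta = np.array([-1.0, 3.0])
        signs = []
        for _ in range(20):
            y = simulate_liability_outcome(X, beta, evals, Q, 0.5, rng)
            fit = fit_phylo_logistic(y, X, corr150, n_boot=0, rng=rng)
            signs.append(fit.coef["b1"] > 0)
        assert np.mean(signs) >= 0.95

    def test_rejects_bad_inputs(self, corr150):
        n = len(corr150.species)
        X = np.ones((n, 1))
        with pytest.raises(ValueError, match="binary"):
            fit_phylo_logistic(np.full(n, 2.0), X, corr150, n_boot=0)
        with pytest.raises(ValueError):
            fit_phylo_logistic(np.zeros(n - 1), X, corr150, n_boot=0)

    def test_non_psd_matrix_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            fit_phylo_logistic(np.array([0.0, 1.0]), np.ones((2, 1)), C, n_boot=0)


class TestPhyloPoisson:
    def test_zero_variance_matches_glm_oracle(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n)])
        counts = rng.poisson(np.exp(X @ np.array([1.0, 0.8])))
        fit = fit_phylo_poisson(counts, X, np.eye(n), sigma2_fixed=0)
        res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(
            np.array(list(fit.coef.values())), res.params, atol=1e-4
        )
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fit.aic == pytest.approx(res.aic, abs=1e-5)

    def test_intercept_only_equal_counts(self):
        t = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        C = correlation_matrix(t, ["A", "B", "C", "D"])
        counts = np.array([7, 7, 7, 7])
        fit = fit_phylo_poisson(counts, np.ones((4, 1)), C, sigma2_fixed=0)
        assert fit.coef["b0"] == pytest.approx(np.log(7), abs=1e-8)

    def test_loglik_monotone_in_covariates(self, corr150, rng):
        n = len(corr150.species)
        x = rng.binomial(1, 0.5, n).astype(float)
        z = rng.standard_normal(n)
        L = np.linalg.cholesky(corr150.matrix + 1e-9 * np.eye(n))
        u = np.sqrt(0.3) * (L @ rng.standard_normal(n))
        counts = rng.poisson(np.exp(1.0 + 1.2 * x + u))
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), x, z])
        f1 = fit_phylo_poisson(counts, X1, corr150)
        f2 = fit_phylo_poisson(counts, X2, corr150)
        assert f2.loglik >= f1.loglik - 1e-6

    def test_all_zero_counts_error(self, corr150):
        n = len(corr150.species)
        with pytest.raises(ValueError, match="zero"):
            fit_phylo_poisson(np.zeros(n), np.ones((n, 1)), corr150)

    def test_parameter_recovery(self, tree150, corr150, rng):
        # true flight-call effect 1.5 and sigma2 = 0.5 recovered within
        # 2 Monte-Carlo standard errors over replicates
        n = len(corr150.species)
        L = np.linalg.cholesky(corr150.matrix + 1e-9 * np.eye(n))
        x = rng.binomial(1, 0.5, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        betas, sig2s = [], []
        for _ in range(25):
            u = np.sqrt(0.5) * (L @ rng.standard_normal(n))
            counts = rng.poisson(np.exp(X @ np.array([1.0, 1.5]) + u))
            fit = fit_phylo_poisson(counts, X, corr150)
            betas.append(fit.coef["b1"])
            sig2s.append(fit.signal)
        for est, truth in ((betas, 1.5), (sig2s, 0.5)):
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) <= 2 * se + 0.05


class TestCompareModels:
    def mkfit(self, aic, k, formula="f"):
        return PhyloGLMFit(
            formula=formula, terms=[], coef={}, signal=0, signal_kind="lambda",
            loglik=-(aic - 2 * k) / 2, aic=aic, n_params=k, n_obs=10,
            outcome_fingerprint=(10, 5.0),
        )

    def test_argmin_and_delta(self):
        comp = compare_models([self.mkfit(100, 2), self.mkfit(90, 3), self.mkfit(95, 4)])
        assert comp.best == 1
        assert comp.delta_aic == [10, 0, 5]

    def test_tie_breaks_toward_fewer_parameters(self):
        comp = compare_models([self.mkfit(90, 3), self.mkfit(90, 4)])
        assert comp.best == 0

    def test_differing_outcomes_rejected(self):
        a = self.mkfit(90, 3)
        b = self.mkfit(91, 3)
        b.outcome_fingerprint = (10, 6.0)
        with pytest.raises(ValueError, match="differing"):
            compare_models([a, b])

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            compare_models([self.mkfit(90, 3)])

    def test_aic_identity(self):
        fit = self.mkfit(100, 2)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
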