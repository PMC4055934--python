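"""AICc competition, mixed and population-level fits, effect sizes,
Cohen's d matrices, and the Mantel test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergekit.inference import (
    ModelFit,
    abs_diff_matrix,
    aicc,
    candidate_models_individual,
    cohens_d_matrix,
    effect_size_r,
    fit_population_regression,
    fit_random_intercept,
    mantel_test,
    rank_models,
)


class TestAicc:
    def test_closed_form_spot_values(self):
        assert aicc(-10, 3, 20) == pytest.approx(27.5)
        assert aicc(0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_boundary_sample_size_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10, 3, 4)  # n = k + 1


def _fit(label, ll, k=3, n=20, terms=()):
    return ModelFit(model_label=label, loglik=ll, k=k, n=n,
                    aicc=aicc(ll, k, n), coefficients={}, terms=terms)


class TestRankModels:
    def test_equal_aicc_gives_equal_weights(self):
        r = rank_models([_fit("a", -10), _fit("b", -10)])
        np.testing.assert_allclose(r.weights, [0.5, 0.5])

    def test_delta_two_weight_ratio(self):
        r = rank_models([_fit("a", -10), _fit("b", -11)])  # delta = 2
        assert r.weights[0] / r.weights[1] == pytest.approx(math.e)
        assert list(r.supported) == [True, True]

    def test_mixed_sample_sizes_rejected(self):
        with pytest.raises(ValueError, match="sample sizes"):
            rank_models([_fit("a", -10, n=20), _fit("b", -10, n=21)])

    def test_ranking_invariant_to_loglik_shift(self):
        fits1 = [_fit("a", -10), _fit("b", -12), _fit("c", -9)]
        fits2 = [_fit(f.model_label, f.loglik + 5) for f in fits1]
        r1, r2 = rank_models(fits1), rank_models(fits2)
        assert [f.model_label for f in r1.fits] == \
               [f.model_label for f in r2.fits]
        np.testing.assert_allclose(r1.delta_aicc, r2.delta_aicc)
        np.testing.assert_allclose(r1.weights, r2.weights)

    @given(st.lists(st.floats(min_value=-50, max_value=-1),
                    min_size=2, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_weights_sum_to_one_and_best_delta_zero(self, logliks):
        r = rank_models([_fit(str(i), ll) for i, ll in enumerate(logliks)])
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert r.delta_aicc[0] == 0.0


class TestRandomIntercept:
    def test_reduces_to_ols_when_between_group_variance_zero(self):
        """With group-centred residuals (zero sample between-group
        variance) the ML mixed fit collapses onto OLS."""
        rng = np.random.default_rng(5)
        n_g, m = 5, 20
        groups = np.repeat(np.arange(n_g), m)
        x = rng.normal(size=n_g * m)
        X = np.column_stack([np.ones(n_g * m), x])
        eps = rng.normal(0, 1, n_g * m)
        for g in range(n_g):
            eps[groups == g] -= eps[groups == g].mean()
        y = 1.0 + 0.5 * x + eps
        fit = fit_random_intercept(y, X, groups, terms=("intercept", "x"))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta_ols) ** 2))
        ll_ols = -0.5 * y.size * (np.log(2 * np.pi * rss / y.size) + 1)
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)
        assert fit.coefficients["x"][0] == pytest.approx(beta_ols[1],
                                                         abs=1e-6)
        assert fit.variance_components["sigma2_group"] < 1e-8

    def test_matches_independent_ml_implementation(self):
        """Log-likelihood and fixed effects agree with statsmodels MixedLM
        fitted by full maximum likelihood."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(42)
        n_g, m = 6, 25
        groups = np.repeat(np.arange(n_g), m)
        x = rng.normal(size=n_g * m)
        u = rng.normal(0, 0.7, n_g)[groups]
        y = 1.0 + 0.5 * x + u + rng.normal(0, 1.0, n_g * m)
        X = np.column_stack([np.ones(n_g * m), x])
        fit = fit_random_intercept(y, X, groups, terms=("intercept", "x"))
        ref = MixedLM(y, X, groups=groups).fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.coefficients["intercept"][0] == pytest.approx(
            ref.fe_params[0], abs=1e-5)
        assert fit.coefficients["x"][0] == pytest.approx(
            ref.fe_params[1], abs=1e-5)

    def test_null_model_intercept_is_grand_mean_when_balanced(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        groups = np.repeat(np.arange(3), 20)
        fit = fit_random_intercept(y, np.ones((60, 1)), groups)
        assert fit.coefficients["intercept"][0] == pytest.approx(
            y.mean(), abs=1e-9)

    def test_slope_recovery(self):
        """beta = 0.5 with 5 groups x 40 individuals: mean estimate over
        200 replicates within 5% of truth."""
        estimates = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            groups = np.repeat(np.arange(5), 40)
            xg = rng.normal(size=5)[groups]
            u = rng.normal(0, 0.3, 5)[groups]
            y = 0.5 * xg + u + rng.normal(0, 1.0, 200)
            X = np.column_stack([np.ones(200), xg])
            fit = fit_random_intercept(y, X, groups,
                                       terms=("intercept", "x"))
            estimates.append(fit.coefficients["x"][0])
        assert abs(np.mean(estimates) - 0.5) < 0.05 * 0.5

    def test_rank_deficient_design_rejected(self):
        y = np.arange(12.0)
        X = np.column_stack([np.ones(12), np.ones(12)])
        with pytest.raises(ValueError, match="rank"):
            fit_random_intercept(y, X, np.repeat([0, 1], 6))


class TestPopulationRegression:
    def test_effect_size_plus_minus_one_for_perfect_line(self):
        x = np.arange(5.0)
        X = np.column_stack([np.ones(5), x])
        y = 2.0 + 0.3 * x + np.array([0.01, -0.01, 0.02, -0.02, 0.0])
        fit = fit_population_regression(y, X, terms=("intercept", "x"))
        assert effect_size_r(fit, "x") > 0.99

    def test_null_loglik_matches_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=8)
        fit = fit_population_regression(y)
        s2 = np.mean((y - y.mean()) ** 2)
        ll = -0.5 * 8 * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik == pytest.approx(ll, abs=1e-9)

    def test_permuted_predictor_has_zero_mean_effect(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=6)
        rs = []
        for _ in range(1000):
            x = rng.permutation(6).astype(float)
            X = np.column_stack([np.ones(6), x])
            fit = fit_population_regression(y, X, terms=("intercept", "x"))
            rs.append(effect_size_r(fit, "x"))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 3 * se


class TestEffectSize:
    def test_zero_t_gives_zero(self):
        fit = ModelFit("m", -1, 3, 20, aicc(-1, 3, 20),
                       {"x": (0.0, 0.0), "intercept": (1.0, 2.0)},
                       kind="ols", terms=("x",))
        assert effect_size_r(fit, "x") == 0.0

    def test_large_t_approaches_one(self):
        fit = ModelFit("m", -1, 3, 20, aicc(-1, 3, 20),
                       {"x": (1.0, 1e8), "intercept": (1.0, 2.0)},
                       kind="ols", terms=("x",))
        assert effect_size_r(fit, "x") == pytest.approx(1.0, abs=1e-12)

    def test_equals_signed_sqrt_r2_for_single_predictor_ols(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.uniform(-2, 2) * x + rng.normal(size=12)
            X = np.column_stack([np.ones(12), x])
            fit = fit_population_regression(y, X, terms=("intercept", "x"))
            ss_res = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
                            ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1 - ss_res / ss_tot
            expected = np.sign(fit.coefficients["x"][0]) * np.sqrt(r2)
            assert effect_size_r(fit, "x") == pytest.approx(expected,
                                                            abs=1e-9)


class TestCohensD:
    def test_equal_means_zero(self):
        pops, mat = cohens_d_matrix({"A": [1, 2, 3], "B": [2, 1, 3]})
        assert mat[0, 1] == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20000)
        b = rng.normal(1, 1, 20000)
        _, mat = cohens_d_matrix({"A": a, "B": b})
        assert mat[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_unequal_n_matches_pooled_sd_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 2, 11), rng.normal(1, 3, 7)
        _, mat = cohens_d_matrix({"A": a, "B": b})
        sp2 = ((10 * a.var(ddof=1) + 6 * b.var(ddof=1)) / 16)
        expected = abs(a.mean() - b.mean()) / math.sqrt(sp2)
        assert mat[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_abs_diff_matrix_for_coefficients(self):
        pops, mat = abs_diff_matrix({"A": 2.5, "B": 2.0, "C": 1.0})
        assert mat[0, 2] == pytest.approx(1.5)
        assert np.allclose(mat, mat.T)


def _random_dist(rng, k=5):
    pts = rng.normal(size=(k, 2))
    return np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))


class TestMantel:
    def test_identical_matrices_r_one_minimum_p(self):
        rng = np.random.default_rng(1)
        A = _random_dist(rng)
        res = mantel_test(A, A)
        assert res.r == pytest.approx(1.0)
        assert res.exhaustive and res.n_permutations_used == 120
        # minimum attainable p: only relabelings preserving the matrix
        assert res.p <= 2 / 120 + 1e-12

    def test_anticorrelated_matrices(self):
        rng = np.random.default_rng(2)
        B = _random_dist(rng)
        A = B.max() - B
        np.fill_diagonal(A, 0)
        res = mantel_test(A, B)
        assert res.r == pytest.approx(-1.0)

    def test_exhaustive_agrees_with_sampled(self):
        rng = np.random.default_rng(3)
        A, B = _random_dist(rng), _random_dist(rng)
        p_ex = mantel_test(A, B).p
        p_s = mantel_test(A, B, n_perm=10_000, seed=9, exhaustive_max=0).p
        assert abs(p_ex - p_s) < 2 / math.sqrt(10_000)

    def test_r_matches_independent_implementation(self):
        """Observed matrix correlation agrees with scikit-bio's Mantel."""
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(4)
        A, B = _random_dist(rng, 6), _random_dist(rng, 6)
        res = mantel_test(A, B)
        r_ref, _, _ = sk_mantel(DistanceMatrix(A), DistanceMatrix(B),
                                permutations=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        A = np.array([[0, 1, 2], [1, 0, 3], [2, 4, 0.0]])
        B = np.zeros((3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(A, A * 0 + A.T)
        with pytest.raises(ValueError):
            mantel_test(np.eye(3), np.eye(3))

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha = 0.05 across 300 independent null
        datasets lies in the exact binomial 95% band."""
        from scipy import stats

        rej = 0
        S = 300
        for s in range(S):
            rng = np.random.default_rng(7000 + s)
            res = mantel_test(_random_dist(rng), _random_dist(rng))
            rej += res.p <= 0.05
        lo, hi = stats.binom.interval(0.95, S, 0.05)
        assert lo <= rej <= hi


class TestModelRecoveryPattern:
    def test_best_model_implicates_generating_index(self):
        """Data generated under a strong sex-ratio effect: the top-ranked
        model contains the sex-ratio term (alone or paired) in at least 90%
        of replicates, and no other sexual index wins."""
        wins = 0
        R = 40
        for rep in range(R):
            rng = np.random.default_rng(4000 + rep)
            pops = [f"P{i}" for i in range(5)]
            idx = {p: {k: rng.uniform(0.5, 2.5)
                       for k in ("sex_ratio", "intrasexual_density",
                                 "total_density", "flight_distance",
                                 "predator_strikes")} for p in pops}
            sr = np.array([idx[p]["sex_ratio"] for p in pops])
            sr_s = (sr - sr.mean()) / sr.std()
            gm = 0.45 * sr_s + rng.normal(0, 0.218, 5)
            y, g = [], []
            for i, p in enumerate(pops):
                y.extend(gm[i] + rng.normal(0, 0.5, 40))
                g.extend([p] * 40)
            ranking = rank_models(candidate_models_individual(
                np.array(y), np.array(g), idx))
            wins += "sex_ratio" in ranking.best().model_label
        assert wins >= 0.9 * R

    def test_null_model_supported_under_null(self):
        """With no index effect (and no residual population structure for a
        spurious predictor to absorb), the null model sits within 2 AICc
        units of the best in at least 60% of replicates."""
        ok = 0
        R = 40
        for rep in range(R):
            rng = np.random.default_rng(5000 + rep)
            pops = [f"P{i}" for i in range(5)]
            idx = {p: {k: rng.uniform(0.5, 2.5)
                       for k in ("sex_ratio", "intrasexual_density",
                                 "total_density", "flight_distance",
                                 "predator_strikes")} for p in pops}
            y, g = [], []
            for i, p in enumerate(pops):
                y.extend(rng.normal(0, 0.5, 40))
                g.extend([p] * 40)
            ranking = rank_models(candidate_models_individual(
                np.array(y), np.array(g), idx))
            ok += ranking.null_supported()
        assert ok >= 0.6 * R
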