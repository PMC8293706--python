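import numpy as np
import pytest
from scipy import stats

import sizeclines as sc
from sizeclines.errors import RankDeficiencyError
from sizeclines.fitrecords import FitRecord
from sizeclines.grids import GridSpec
from sizeclines.sar import (
    build_weights, classify_latitudinal_pattern, fit_ols, fit_sar_error,
    nagelkerke_r2, sar_error_loglik,
)


def dense_sar_loglik(lam, y, X, W):
    """Brute-force oracle: explicit (I - lam W) inversion and MVN density.

    The error covariance is sigma^2 (A'A)^{-1}; beta and sigma^2 are
    profiled with the textbook GLS formulas on dense matrices.
    """
    n = len(y)
    A = np.eye(n) - lam * W
    AtA = A.T @ A
    beta = np.linalg.solve(X.T @ AtA @ X, X.T @ AtA @ y)
    r = y - X @ beta
    sigma2 = float(r @ AtA @ r) / n
    cov = sigma2 * np.linalg.inv(AtA)
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=cov)


class TestWeights:
    def test_2x2_rook_has_two_neighbors_each(self):
        g = GridSpec(2, 2)
        w = build_weights(g.cell_ids(), g, scheme="rook", standardize=False)
        assert (w.W.sum(axis=1) == 2).all()

    def test_2x2_queen_has_three_neighbors_each(self):
        g = GridSpec(2, 2)
        w = build_weights(g.cell_ids(), g, scheme="queen", standardize=False)
        assert (w.W.sum(axis=1) == 3).all()

    def test_row_standardized_weights(self):
        g = GridSpec(2, 2)
        w = build_weights(g.cell_ids(), g, scheme="queen")
        np.testing.assert_allclose(w.W[w.W > 0], 1 / 3)
        np.testing.assert_allclose(w.W.sum(axis=1), 1.0)

    def test_single_cell_warns(self):
        g = GridSpec(3, 3)
        with pytest.warns(UserWarning, match="no neighbors"):
            build_weights(np.array([4]), g)

    def test_binary_neighborhood_is_symmetric(self):
        g = GridSpec(5, 7)
        cells = np.array([0, 1, 2, 8, 9, 16, 30, 31])
        w = build_weights(cells, g, standardize=False)
        assert np.array_equal(w.W, w.W.T)


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = fit_ols(2 * x, np.column_stack([np.ones(10), x]),
                      ["intercept", "x"])
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-12)
        assert fit.extras["sigma2"] == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_fits_the_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = fit_ols(y, np.ones((3, 1)), ["intercept"])
        assert fit.coef("intercept") == pytest.approx(y.mean())

    def test_loglik_matches_density_sum_oracle(self):
        rng = np.random.default_rng(0)
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        fit = fit_ols(y, X)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sigma = np.sqrt(((y - X @ beta) ** 2).sum() / n)
        oracle = stats.norm.logpdf(y, X @ beta, sigma).sum()
        assert fit.loglik == pytest.approx(oracle, abs=1e-8)

    def test_rank_deficiency_names_offenders(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_ols(np.arange(10.0), X, ["intercept", "dup"])


class TestSAREstimator:
    def test_profiled_loglik_matches_dense_oracle(self):
        """21-point lambda grid on a 5-cell problem, 1e-8 agreement."""
        g = GridSpec(3, 3)
        cells = np.array([0, 1, 3, 4, 7])
        W = build_weights(cells, g)
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        y = rng.normal(size=5)
        lo, hi = W.lambda_interval()
        for lam in np.linspace(lo + 0.01, hi - 0.01, 21):
            mine = sar_error_loglik(lam, y, X, W)
            oracle = dense_sar_loglik(lam, y, X, W.W)
            assert mine == pytest.approx(oracle, abs=1e-8)

    def test_lambda_zero_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        g = GridSpec(5, 5)
        W = build_weights(g.cell_ids(), g)
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = X @ [1.0, 0.5] + rng.normal(size=25)
        sar = fit_sar_error(y, X, W, ["intercept", "x"], lambda_mode=0.0)
        ols = fit_ols(y, X, ["intercept", "x"])
        np.testing.assert_allclose(sar.beta, ols.beta, atol=1e-8)
        assert sar.loglik == pytest.approx(ols.loglik, abs=1e-8)

    def test_iid_data_estimates_lambda_near_zero(self):
        rng = np.random.default_rng(3)
        g = GridSpec(20, 20)
        W = build_weights(g.cell_ids(), g)
        X = np.column_stack([np.ones(400), rng.normal(size=400)])
        y = X @ [1.0, 0.5] + rng.normal(0, 0.5, 400)
        sar = fit_sar_error(y, X, W, ["intercept", "x"])
        ols = fit_ols(y, X, ["intercept", "x"])
        assert abs(sar.extras["lambda_sp"]) < 0.1
        assert abs(sar.coef("x") - ols.coef("x")) < 2 * ols.coef_se("x")

    def test_strong_autocorrelation_recovered(self):
        g = GridSpec(20, 20)
        W = build_weights(g.cell_ids(), g)
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(400), rng.normal(size=400)])
        u = np.linalg.solve(np.eye(400) - 0.8 * W.W, rng.normal(0, 0.3, 400))
        fit = fit_sar_error(X @ [1.0, 0.5] + u, X, W, ["intercept", "x"])
        assert fit.extras["lambda_sp"] == pytest.approx(0.8, abs=0.15)

    def test_pseudo_r2_recorded_and_bounded(self, small_dataset):
        from sizeclines.assemblage import build_assemblage_table
        from sizeclines.sar import design_matrix

        tab = build_assemblage_table(small_dataset["pam"],
                                     small_dataset["traits"],
                                     small_dataset["climate"], 1)
        W = build_weights(tab, small_dataset["grid"])
        y, X, terms = design_matrix(tab, list(sc.CLIMATE_VARS))
        fit = fit_sar_error(y, X, W, terms)
        assert 0.0 <= fit.extras["pseudo_r2"] < 1.0
        assert fit.extras["loglik_null"] <= fit.loglik


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        assert nagelkerke_r2(-10.0, -10.0, 50) == 0.0

    def test_closed_form_value(self):
        assert nagelkerke_r2(-90.0, -100.0, 100) == pytest.approx(
            1 - np.exp(-0.2), abs=1e-12)

    def test_monotone_and_shift_invariant(self):
        base = nagelkerke_r2(-90.0, -100.0, 100)
        assert nagelkerke_r2(-85.0, -100.0, 100) > base
        assert nagelkerke_r2(-90.0 + 7.3, -100.0 + 7.3, 100) == pytest.approx(base)

    def test_huge_difference_approaches_one(self):
        assert nagelkerke_r2(0.0, -1e6, 10) < 1.0
        assert nagelkerke_r2(0.0, -1e6, 10) == pytest.approx(1.0, abs=1e-9)

    def test_model_below_null_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert nagelkerke_r2(-101.0, -100.0, 50) == 0.0

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-1.0, -2.0, 0)


def _lat_fit(slope, p):
    return FitRecord(terms=["intercept", "lat"],
                     beta=np.array([0.0, slope]), se=np.array([1.0, 1.0]),
                     stat=np.array([0.0, 0.0]),
                     pvalues=np.array([1.0, p]), loglik=0.0, n=100)


@pytest.mark.parametrize(
    "slope,p,expected",
    [
        (-0.004, 0.0005, "inverse_bergmann"),  # all lizards, assemblage level
        (0.008, 0.0005, "bergmann"),           # lacertids, assemblage level
        (-0.001, 0.842, "none"),               # all lizards, species level
    ],
)
def test_latitudinal_pattern_classification(slope, p, expected):
    assert classify_latitudinal_pattern(_lat_fit(slope, p)) == expected
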