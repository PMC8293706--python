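import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sizeclines.errors import NestingViolationError
from sizeclines.mixedmodel import drop_widest_ranging, fit_nested_lmm
from sizeclines.sar import fit_ols


def _balanced(n_fam=6, n_gen=3, n_sp=4, vf=0.0, vg=0.0, vr=0.1, seed=0):
    rng = np.random.default_rng(seed)
    n = n_fam * n_gen * n_sp
    fam = np.repeat([f"f{i}" for i in range(n_fam)], n_gen * n_sp)
    gen = np.repeat([f"f{i}g{j}" for i in range(n_fam) for j in range(n_gen)],
                    n_sp)
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = (1.0 + 0.5 * x
         + np.repeat(rng.normal(0, np.sqrt(vf), n_fam), n_gen * n_sp)
         + np.repeat(rng.normal(0, np.sqrt(vg), n_fam * n_gen), n_sp)
         + rng.normal(0, np.sqrt(vr), n))
    return y, X, fam, gen


class TestNestedLMM:
    def test_zero_variance_components_approach_ols(self):
        """Data with no group structure: components shrink toward the 0
        boundary and fixed effects agree with OLS (REML never lands exactly
        on the boundary, so agreement is statistical, not bitwise)."""
        y, X, fam, gen = _balanced(n_fam=12, n_gen=4, n_sp=5,
                                   vf=0.0, vg=0.0, vr=0.1, seed=1)
        lmm = fit_nested_lmm(y, X, fam, gen, terms=["intercept", "x"])
        ols = fit_ols(y, X, ["intercept", "x"])
        np.testing.assert_allclose(lmm.beta, ols.beta, atol=0.02)
        assert lmm.extras["var_family"] < 0.02
        assert lmm.extras["var_genus"] < 0.02

    def test_degenerate_single_group_is_exactly_ols(self):
        """With one family and one genus the model *is* OLS, bit for bit."""
        rng = np.random.default_rng(7)
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(0, 0.3, n)
        with pytest.warns(UserWarning, match="single family"):
            lmm = fit_nested_lmm(y, X, np.repeat("f", n), np.repeat("g", n),
                                 terms=["intercept", "x"])
        ols = fit_ols(y, X, ["intercept", "x"])
        np.testing.assert_allclose(lmm.beta, ols.beta, atol=1e-12)
        assert lmm.extras["var_family"] == 0.0 and lmm.extras["var_genus"] == 0.0

    def test_ml_loglik_matches_dense_covariance_oracle(self):
        """llf equals the MVN density with the implied block covariance."""
        y, X, fam, gen = _balanced(n_fam=3, n_gen=2, n_sp=5,
                                   vf=0.3, vg=0.2, vr=0.1, seed=2)
        fit = fit_nested_lmm(y, X, fam, gen, terms=["intercept", "x"],
                             method="ml")
        Zf = pd.get_dummies(pd.Series(fam)).to_numpy(float)
        Zg = pd.get_dummies(pd.Series(gen)).to_numpy(float)
        Sigma = (fit.extras["var_family"] * Zf @ Zf.T
                 + fit.extras["var_genus"] * Zg @ Zg.T
                 + fit.extras["var_resid"] * np.eye(len(y)))
        oracle = stats.multivariate_normal.logpdf(y, mean=X @ fit.beta,
                                                  cov=Sigma)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_component_recovery_on_balanced_design(self):
        from sizeclines.validation import lmm_component_recovery

        out = lmm_component_recovery(n_reps=25, seed=3)
        assert out["max_abs_rel_bias"] < 0.25

    def test_genus_under_two_families_rejected(self):
        y, X, fam, gen = _balanced(seed=4)
        fam = fam.copy()
        fam[0] = "f9"  # first genus now spans f9 and f0
        with pytest.raises(NestingViolationError):
            fit_nested_lmm(y, X, fam, gen)

    def test_all_singleton_genera_warn(self):
        rng = np.random.default_rng(5)
        n = 24
        fam = np.repeat(["a", "b", "c"], 8)
        gen = np.array([f"g{i}" for i in range(n)])
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(0, 0.3, n)
        with pytest.warns(UserWarning, match="singleton"):
            fit = fit_nested_lmm(y, X, fam, gen, terms=["intercept", "x"])
        assert fit.extras["var_genus"] >= 0.0

    def test_single_family_group_uses_genus_only_structure(self):
        y, X, fam, gen = _balanced(n_fam=1, n_gen=6, n_sp=5,
                                   vg=0.2, vr=0.1, seed=6)
        fit = fit_nested_lmm(y, X, fam, gen, terms=["intercept", "x"])
        assert fit.extras["var_family"] == 0.0
        assert fit.extras["var_genus"] > 0.0


class TestRangeFilter:
    def _traits(self, n):
        return pd.DataFrame({"species": [f"sp{i:02d}" for i in range(n)],
                             "log10_mass_g": np.linspace(1, 2, n)})

    def test_ten_species_drops_exactly_the_largest(self):
        traits = self._traits(10)
        sizes = pd.Series(range(1, 11), index=traits["species"])
        out = drop_widest_ranging(traits, sizes, 0.10)
        assert len(out) == 9
        assert "sp09" not in set(out["species"])

    def test_fraction_zero_is_identity(self):
        traits = self._traits(7)
        sizes = pd.Series(range(7), index=traits["species"])
        pd.testing.assert_frame_equal(
            drop_widest_ranging(traits, sizes, 0.0), traits)

    def test_ceiling_convention_with_eleven_species(self):
        traits = self._traits(11)
        sizes = pd.Series(range(1, 12), index=traits["species"])
        out = drop_widest_ranging(traits, sizes, 0.10)
        assert len(out) == 9  # ceil(1.1) = 2 removed
        assert {"sp09", "sp10"}.isdisjoint(out["species"])

    def test_ties_retain_lexicographically_smallest_ids(self):
        traits = self._traits(4)
        sizes = pd.Series([5, 5, 5, 1], index=traits["species"])
        out = drop_widest_ranging(traits, sizes, 0.25)  # remove one of the 5s
        assert "sp02" not in set(out["species"])
        assert {"sp00", "sp01", "sp03"} <= set(out["species"])

    @pytest.mark.parametrize("n,frac", [(10, 0.1), (23, 0.1), (23, 0.37), (5, 0.0)])
    def test_output_size_formula(self, n, frac):
        import math

        traits = self._traits(n)
        sizes = pd.Series(range(n), index=traits["species"])
        assert len(drop_widest_ranging(traits, sizes, frac)) == n - math.ceil(frac * n)

    def test_invalid_fraction_rejected(self):
        traits = self._traits(3)
        sizes = pd.Series(range(3), index=traits["species"])
        with pytest.raises(ValueError):
            drop_widest_ranging(traits, sizes, 1.0)
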