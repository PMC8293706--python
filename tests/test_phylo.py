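import dendropy
import numpy as np
import pandas as pd
import pytest

import sizeclines as sc
from sizeclines.errors import AlignmentError, InvalidGridError
from sizeclines.phylo import (
    assign_taxonomy, lambda_transform, phylo_covariance, read_tree,
    simulate_phylogeny, simulate_traits, write_tree,
)


def _tip_depths(tree):
    return {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}


class TestYuleSimulation:
    def test_two_tips_is_a_unit_depth_cherry(self):
        tree = simulate_phylogeny(2, seed=0)
        depths = _tip_depths(tree)
        assert len(depths) == 2
        assert all(d == pytest.approx(1.0, abs=1e-12) for d in depths.values())

    def test_binary_tree_internal_node_count(self):
        tree = simulate_phylogeny(50, seed=1)
        internals = sum(1 for _ in tree.postorder_internal_node_iter())
        assert internals == 49

    def test_ultrametric_within_tolerance(self):
        tree = simulate_phylogeny(30, seed=2)
        d = list(_tip_depths(tree).values())
        assert max(d) - min(d) < 1e-8

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidGridError):
            simulate_phylogeny(1, seed=0)

    def test_newick_round_trip(self, tmp_path):
        tree = simulate_phylogeny(10, seed=3)
        write_tree(tree, tmp_path / "t.nwk")
        back = read_tree(tmp_path / "t.nwk")
        sp = sorted(l.taxon.label for l in back.leaf_node_iter())
        assert sp == [f"sp{i:04d}" for i in range(10)]
        C1 = phylo_covariance(tree, sp)
        C2 = phylo_covariance(back, sp)
        np.testing.assert_allclose(C1, C2, atol=1e-10)


class TestPhyloCovariance:
    def test_root_divergence_gives_identity(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        C = phylo_covariance(tree, ["A", "B"])
        np.testing.assert_allclose(C, np.eye(2), atol=1e-12)

    def test_cherry_shared_branch(self):
        tree = dendropy.Tree.get(
            data="((A:0.4,B:0.4):0.6,C:1.0);", schema="newick")
        C = phylo_covariance(tree, ["A", "B", "C"])
        expected = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]])
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_missing_species_listed(self):
        tree = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        with pytest.raises(KeyError, match="ZZZ"):
            phylo_covariance(tree, ["A", "ZZZ"])

    def test_positive_semidefinite_over_random_trees(self):
        for seed in range(100):
            tree = simulate_phylogeny(20, seed=seed)
            sp = sorted(l.taxon.label for l in tree.leaf_node_iter())
            C = phylo_covariance(tree, sp)
            assert np.linalg.eigvalsh(C).min() > -1e-10
            np.linalg.cholesky(C)  # succeeds with zero jitter


class TestLambdaTransform:
    def test_extremes_and_midpoint(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        np.testing.assert_allclose(lambda_transform(C, 0.0), np.eye(2))
        assert lambda_transform(C, 0.5)[0, 1] == pytest.approx(0.3)

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, lam):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), lam)


class TestTraitSimulation:
    def _climate(self, species):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            {v: rng.normal(size=len(species)) for v in sc.CLIMATE_VARS},
            index=pd.Index(species, name="species"))

    def test_noise_free_traits_equal_linear_predictor(self):
        tree = simulate_phylogeny(12, seed=4)
        sp = sorted(l.taxon.label for l in tree.leaf_node_iter())
        clim = self._climate(sp)
        beta = np.array([1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        traits = simulate_traits(tree, clim, beta, sigma_phylo=0.0,
                                 sigma_resid=0.0, seed=0)
        X = np.column_stack([np.ones(12), clim.loc[sp].to_numpy()])
        np.testing.assert_allclose(
            traits.set_index("species").loc[sp, "log10_mass_g"], X @ beta,
            atol=1e-12)

    def test_fixed_seed_reproducible(self):
        tree = simulate_phylogeny(10, seed=6)
        sp = sorted(l.taxon.label for l in tree.leaf_node_iter())
        clim = self._climate(sp)
        t1 = simulate_traits(tree, clim, np.zeros(6), seed=7)
        t2 = simulate_traits(tree, clim, np.zeros(6), seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_mismatched_species_sets_rejected(self):
        tree = simulate_phylogeny(5, seed=8)
        clim = self._climate(["x1", "x2"])
        with pytest.raises(AlignmentError):
            simulate_traits(tree, clim, np.zeros(6), seed=0)

    def test_monte_carlo_covariance_matches_brownian_model(self):
        """Sample covariance over replicates converges to sigma^2 C(lambda)."""
        n_tips, n_reps = 8, 2000
        tree = simulate_phylogeny(n_tips, seed=9)
        sp = sorted(l.taxon.label for l in tree.leaf_node_iter())
        clim = self._climate(sp)
        sigma = 0.5
        C = phylo_covariance(tree, sp)
        draws = np.empty((n_reps, n_tips))
        for r in range(n_reps):
            t = simulate_traits(tree, clim, np.zeros(6), sigma_phylo=sigma,
                                sigma_resid=0.0, lambda_true=1.0, seed=100 + r)
            draws[r] = t.set_index("species").loc[sp, "log10_mass_g"]
        S = np.cov(draws.T)
        target = sigma**2 * C
        rel_err = np.linalg.norm(S - target) / np.linalg.norm(target)
        assert rel_err < 0.10


class TestTaxonomyAssignment:
    def test_families_partition_tips_and_nesting_is_strict(self):
        tree = simulate_phylogeny(60, seed=10)
        tax = assign_taxonomy(tree, n_families=4, genera_per_family=3)
        assert len(tax) == 60
        assert tax["species"].is_unique
        assert tax["family"].nunique() == 4
        fams_per_genus = tax.groupby("genus")["family"].nunique()
        assert (fams_per_genus == 1).all()
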