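"""Phylogeny simulation, phylogenetic covariance, and trait simulation.

Trees are pure-birth (Yule) simulations rescaled to unit root depth, so
the phylogenetic covariance matrix C (shared branch length from the root
to the most recent common ancestor of each species pair) has unit
diagonal.  Species body sizes are generated as

    log10_mass = X @ beta + u + eps

with ``u ~ MVN(0, sigma_phylo^2 * C(lambda))`` — C's off-diagonals scaled
by Pagel's lambda, exactly the transform the PGLS estimator uses — and
``eps`` independent Gaussian noise.  Setting ``sigma_resid = 0`` makes the
generative model identical to the PGLS working model.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .allometry import load_allometry, coefficients_for, mass_to_svl
from .errors import AlignmentError, InvalidGridError, MissingSpeciesError
from .grids import CLIMATE_VARS

__all__ = [
    "simulate_phylogeny",
    "phylo_covariance",
    "lambda_transform",
    "assign_taxonomy",
    "simulate_traits",
    "read_tree",
    "write_tree",
]


def simulate_phylogeny(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree on ``n_tips`` species, rescaled to root depth 1.

    Waiting times between births are Exponential(k) with k the current
    lineage count, plus one final Exponential(n) stretch after the last
    birth so every terminal branch has positive length (the covariance
    matrix stays positive definite).  The tree is ultrametric by
    construction.  Tips are labeled ``sp0000 ... spNNNN`` to match the
    species ids produced by the range generator.
    """
    if n_tips < 2:
        raise InvalidGridError(f"a phylogeny needs at least 2 tips, got {n_tips}")
    rng = np.random.default_rng(int(seed))
    tree = dendropy.Tree()
    root = tree.seed_node
    root.edge.length = 0.0
    root._birth = 0.0
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child._birth = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - node._birth
        for _ in range(2):
            child = dendropy.Node()
            child._birth = t
            node.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    for leaf in active:
        leaf.edge.length = t_end - leaf._birth
    # rescale to unit root depth and attach taxa in a stable order
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= t_end
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(label=f"sp{i:04d}")
    return tree


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _node_depths(tree: dendropy.Tree) -> None:
    """Attach root-to-node distance as ``node._depth`` (single traversal)."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._depth = 0.0
        else:
            node._depth = node.parent_node._depth + (node.edge.length or 0.0)


def phylo_covariance(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Shared-branch-length matrix: C[i,j] = depth of MRCA(i, j).

    The diagonal is each species' root-to-tip distance.  ``species`` orders
    the rows/columns and must be a subset of the tree's tip labels.
    """
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise MissingSpeciesError(f"species absent from tree: {missing}")
    index = {s: i for i, s in enumerate(species)}
    wanted = set(species)

    _node_depths(tree)
    n = len(species)
    C = np.zeros((n, n))
    for s in species:
        i = index[s]
        C[i, i] = tips[s]._depth
    # postorder: the first node joining two tips is their MRCA
    for node in tree.postorder_internal_node_iter():
        child_sets = []
        for child in node.child_nodes():
            if child.is_leaf():
                lbl = child.taxon.label
                child_sets.append([index[lbl]] if lbl in wanted else [])
            else:
                child_sets.append(child._tipidx)
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        C[i, j] = C[j, i] = node._depth
        node._tipidx = [i for s in child_sets for i in s]
    return C


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: scale C's off-diagonal entries, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def assign_taxonomy(
    tree: dendropy.Tree, n_families: int = 4, genera_per_family: int = 3
) -> pd.DataFrame:
    """Carve the tree into families of comparable size and nested genera.

    Clades larger than n_tips / n_families are split top-down; the resulting
    clades are then merged smallest-first into exactly ``n_families`` family
    labels.  Families are therefore unions of one or more clades — roughly
    balanced in size, occasionally paraphyletic, as real family-level
    taxonomies sometimes are.  Genera nest strictly inside families.
    Returns a DataFrame with columns species, family, genus.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    target = max(1, int(np.ceil(n_tips / n_families)))

    def n_leaves(nd):
        return sum(1 for _ in nd.leaf_iter())

    clades = [tree.seed_node]
    while True:
        clades.sort(key=n_leaves, reverse=True)
        big = clades[0]
        if n_leaves(big) <= target or big.is_leaf():
            break
        clades = clades[1:] + big.child_nodes()
    # merge smallest-first into n_families bins (each bin: list of clades)
    bins = [[c] for c in clades]
    while len(bins) > n_families:
        bins.sort(key=lambda b: sum(n_leaves(c) for c in b))
        small = bins.pop(0)
        bins[0] = bins[0] + small
        bins.sort(key=lambda b: sum(n_leaves(c) for c in b))

    def first_label(b):
        return min(l.taxon.label for c in b for l in c.leaf_iter())

    rows = []
    for fi, fam_bin in enumerate(sorted(bins, key=first_label)):
        fam_name = f"fam{fi:02d}"
        gen_clades = list(fam_bin)
        max_genera = sum(n_leaves(c) for c in fam_bin)
        while len(gen_clades) < min(genera_per_family, max_genera):
            gen_clades.sort(key=n_leaves, reverse=True)
            big = gen_clades[0]
            if big.is_leaf():
                break
            gen_clades = gen_clades[1:] + big.child_nodes()
        for gi, gen in enumerate(sorted(gen_clades,
                                        key=lambda c: first_label([c]))):
            gen_name = f"{fam_name}_gen{gi:02d}"
            for leaf in gen.leaf_iter():
                rows.append((leaf.taxon.label, fam_name, gen_name))
    return (
        pd.DataFrame(rows, columns=["species", "family", "genus"])
        .sort_values("species")
        .reset_index(drop=True)
    )


def simulate_traits(
    tree: dendropy.Tree,
    species_climate: pd.DataFrame,
    beta,
    sigma_phylo: float = 0.25,
    sigma_resid: float = 0.05,
    lambda_true: float = 0.9,
    seed: int = 0,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate a trait table with known climate effects and phylogenetic signal.

    Parameters
    ----------
    species_climate
        DataFrame indexed by species id with the five climate columns
        (typically from :func:`sizeclines.assemblage.species_climate_summary`).
    beta
        Coefficient vector ``[intercept, MAT, TS, AP, PS, NPP]`` applied to
        all species, or a mapping family -> vector for group-specific effects
        (requires ``taxonomy`` or uses the tree-derived default).
    sigma_phylo, sigma_resid
        SD of the Brownian (phylogenetically structured) and independent
        residual components, on the log10-gram scale.
    lambda_true
        Pagel's lambda applied to the phylogenetic covariance at simulation
        time, exactly as the PGLS estimator applies it.
    """
    if sigma_phylo < 0 or sigma_resid < 0:
        raise ValueError("sigma_phylo and sigma_resid must be >= 0")
    tip_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    missing = set(tip_labels) - set(species_climate.index)
    if missing:
        raise AlignmentError(
            f"species in tree but not in climate summary: {sorted(missing)}"
        )
    species = tip_labels
    clim = species_climate.loc[species, list(CLIMATE_VARS)]
    X = np.column_stack([np.ones(len(species)), clim.to_numpy(float)])

    if taxonomy is None:
        taxonomy = assign_taxonomy(tree)
    taxonomy = taxonomy.set_index("species").loc[species]

    if isinstance(beta, dict):
        mean = np.empty(len(species))
        for i, sp in enumerate(species):
            fam = taxonomy.loc[sp, "family"]
            if fam not in beta:
                raise AlignmentError(f"no beta vector for family {fam!r}")
            mean[i] = X[i] @ np.asarray(beta[fam], dtype=float)
    else:
        mean = X @ np.asarray(beta, dtype=float)

    rng = np.random.default_rng(seed)
    if sigma_phylo > 0:
        C = phylo_covariance(tree, species)
        V = lambda_transform(C, lambda_true) * sigma_phylo**2
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(species)))
        u = L @ rng.standard_normal(len(species))
    else:
        u = np.zeros(len(species))
    eps = rng.normal(0.0, sigma_resid, len(species)) if sigma_resid > 0 else 0.0
    log10_mass = mean + u + eps

    allom = load_allometry()
    svl = np.array(
        [
            mass_to_svl(m, coefficients_for(fam, allom))
            for m, fam in zip(log10_mass, taxonomy["family"])
        ]
    )
    return pd.DataFrame(
        {
            "species": species,
            "family": taxonomy["family"].to_numpy(),
            "genus": taxonomy["genus"].to_numpy(),
            "max_svl_mm": svl,
            "log10_mass_g": log10_mass,
            "in_tree": True,
        }
    )
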