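"""Orchestration: simulate -> assemble -> fit -> null model -> report.

A single YAML config drives everything.  In simulation mode the config
carries the full synthetic-data parameterization (grid, ranges, phylogeny,
trait model, seeds); in path mode it points at existing CSV/Newick inputs.
``run_full_analysis`` executes, for all species and per configured group:
the assemblage spatial-error SAR (five climate predictors, and
latitude-only), the trait-randomization reliability test, species-level
PGLS (five-predictor and latitude-only), and the nested LMM with and
without the wide-range filter, then emits tidy tables, two summary tables
(latitudinal gradients; multivariate climate fits) and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assemblage import build_assemblage_table, species_climate_summary
from .errors import EmptyAnalysisError
from .grids import (
    CLIMATE_VARS, ClimateGrid, GridSpec, PresenceAbsenceMatrix,
    generate_climate_grid, generate_ranges,
)
from .mixedmodel import drop_widest_ranging, fit_nested_lmm
from .nullmodel import null_reliability_test
from .pgls import fit_pgls
from .phylo import read_tree, simulate_phylogeny, simulate_traits, write_tree
from .sar import build_weights, classify_latitudinal_pattern, design_matrix, fit_sar_error

log = logging.getLogger("sizeclines")

PREDICTORS = list(CLIMATE_VARS)


@dataclass
class AnalysisConfig:
    """Everything a full run needs; exactly one of simulation/paths."""

    simulation: dict | None = None
    paths: dict | None = None
    min_richness: int = 1
    weights_scheme: str = "queen"
    n_rand: int = 100
    alpha: float = 0.05
    null_method: str = "ttest"
    range_filter_fraction: float = 0.10
    groups: dict[str, list[str]] | None = None  # group name -> families
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.paths is None):
            raise ValueError("exactly one of 'simulation' or 'paths' is required")
        if self.simulation is not None and "seed" in self.simulation:
            self.seed = int(self.simulation["seed"])

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class Dataset:
    """In-memory bundle of one analysis' inputs."""

    grid: GridSpec
    climate: ClimateGrid
    pam: PresenceAbsenceMatrix
    tree: object  # dendropy.Tree
    traits: pd.DataFrame
    species_climate: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.species_climate is None:
            self.species_climate = species_climate_summary(self.pam, self.climate)


def simulate_dataset(cfg: AnalysisConfig) -> Dataset:
    """Generate landscape, ranges, phylogeny and traits from the config."""
    sim = dict(cfg.simulation or {})
    seed = int(sim.get("seed", cfg.seed))
    grid = GridSpec(
        n_rows=int(sim.get("n_rows", 20)),
        n_cols=int(sim.get("n_cols", 20)),
        lat_min=float(sim.get("lat_min", 18.0)),
        lon_min=float(sim.get("lon_min", 75.0)),
        resolution=float(sim.get("resolution", 1.0)),
    )
    climate = generate_climate_grid(
        grid,
        trend_slopes=sim.get("trend_slopes"),
        intercepts=sim.get("intercepts"),
        noise_sd=sim.get("noise_sd"),
        smoothing_radius=int(sim.get("smoothing_radius", 2)),
        seed=seed,
    )
    n_species = int(sim.get("n_species", 120))
    pam = generate_ranges(
        climate,
        n_species=n_species,
        range_size_distribution=tuple(sim.get("range_size", (5, 40))),
        niche_breadth=sim.get("niche_breadth", "none"),
        seed=seed + 1,
    )
    tree = simulate_phylogeny(n_species, seed=seed + 2)
    sp_clim = species_climate_summary(pam, climate)
    beta = sim.get("beta", [1.0, 0.02, 0.0, 0.0, 0.0, 0.0])
    if isinstance(beta, dict):
        beta = {k: list(map(float, v)) for k, v in beta.items()}
    from .phylo import assign_taxonomy

    taxonomy = assign_taxonomy(
        tree,
        n_families=int(sim.get("n_families", 4)),
        genera_per_family=int(sim.get("genera_per_family", 4)),
    )
    traits = simulate_traits(
        tree,
        sp_clim,
        beta=beta,
        sigma_phylo=float(sim.get("sigma_phylo", 0.25)),
        sigma_resid=float(sim.get("sigma_resid", 0.05)),
        lambda_true=float(sim.get("lambda_true", 0.9)),
        seed=seed + 3,
        taxonomy=taxonomy,
    )
    return Dataset(grid=grid, climate=climate, pam=pam, tree=tree,
                   traits=traits, species_climate=sp_clim)


def load_dataset(cfg: AnalysisConfig) -> Dataset:
    """Read climate/ranges/tree/traits from the configured paths."""
    p = cfg.paths
    grid = GridSpec(
        n_rows=int(p["n_rows"]), n_cols=int(p["n_cols"]),
        lat_min=float(p.get("lat_min", 18.0)),
        lon_min=float(p.get("lon_min", 75.0)),
        resolution=float(p.get("resolution", 1.0)),
    )
    climate = ClimateGrid.read_csv(p["climate"], grid)
    pam = PresenceAbsenceMatrix.read_csv(p["pam"], grid)
    tree = read_tree(p["tree"]) if p.get("tree") else None
    traits = pd.read_csv(p["traits"])
    return Dataset(grid=grid, climate=climate, pam=pam, tree=tree, traits=traits)


def get_dataset(cfg: AnalysisConfig) -> Dataset:
    return simulate_dataset(cfg) if cfg.simulation is not None else load_dataset(cfg)


def write_dataset(data: Dataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.climate.write_csv(outdir / "climate.csv")
    data.pam.write_csv(outdir / "pam.csv")
    if data.tree is not None:
        write_tree(data.tree, outdir / "tree.nwk")
    data.traits.to_csv(outdir / "traits.csv", index=False)
    data.species_climate.to_csv(outdir / "species_climate.csv")


def _group_species(data: Dataset, families: list[str]) -> list[str]:
    mask = data.traits["family"].isin(families)
    return sorted(data.traits.loc[mask, "species"])


def analyze_group(
    name: str,
    species: list[str],
    data: Dataset,
    cfg: AnalysisConfig,
    seed: int,
    run_null: bool = True,
) -> dict | None:
    """All analyses for one species group; None when the group is too small.

    Refitting a group standalone reproduces the orchestrated numbers: the
    group's assemblage and weights are rebuilt from its own presence-absence
    subset, with no information shared across groups.
    """
    n_pred = len(PREDICTORS)
    if len(species) < n_pred + 2:
        log.warning("group %s skipped: %d species < %d predictors + 2",
                    name, len(species), n_pred)
        return None
    pam_g = data.pam.subset_species(species)
    traits_g = data.traits[data.traits["species"].isin(species)].reset_index(drop=True)
    out: dict = {"group": name, "n_species": len(species)}

    # assemblage level
    try:
        tab = build_assemblage_table(pam_g, traits_g, data.climate, cfg.min_richness)
    except EmptyAnalysisError as err:
        log.warning("group %s skipped at assemblage level: %s", name, err)
        return None
    W = build_weights(tab, data.grid, scheme=cfg.weights_scheme)
    y, X, terms = design_matrix(tab, PREDICTORS)
    out["assemblage_table"] = tab
    out["sar_climate"] = fit_sar_error(y, X, W, terms)
    y_l, X_l, t_l = design_matrix(tab, ["lat"])
    out["sar_lat"] = fit_sar_error(y_l, X_l, W, t_l)
    out["lat_pattern"] = classify_latitudinal_pattern(out["sar_lat"], cfg.alpha, "lat")
    if run_null and cfg.n_rand > 0:
        out["null"] = null_reliability_test(
            pam_g, traits_g, data.climate, W=W, predictors=tuple(PREDICTORS),
            min_richness=cfg.min_richness, n_rand=cfg.n_rand, alpha=cfg.alpha,
            seed=seed, method=cfg.null_method,
        )

    # species level: PGLS on the species present in the tree
    sp_clim = data.species_climate.loc[species]
    in_tree = traits_g.set_index("species")["in_tree"]
    tree_species = [s for s in species if bool(in_tree.loc[s])] if data.tree else []
    if len(tree_species) >= n_pred + 2:
        tt = traits_g.set_index("species").loc[tree_species]
        Xs = np.column_stack(
            [np.ones(len(tree_species)), sp_clim.loc[tree_species, PREDICTORS].to_numpy(float)]
        )
        ys = tt["log10_mass_g"].to_numpy(float)
        out["pgls_climate"] = fit_pgls(
            ys, Xs, data.tree, species=tree_species, terms=["intercept"] + PREDICTORS
        )
        Xl = np.column_stack(
            [np.ones(len(tree_species)), sp_clim.loc[tree_species, "centroid_lat"].to_numpy(float)]
        )
        out["pgls_lat"] = fit_pgls(
            ys, Xl, data.tree, species=tree_species, terms=["intercept", "lat"]
        )
        out["pgls_lat_pattern"] = classify_latitudinal_pattern(
            out["pgls_lat"], cfg.alpha, "lat"
        )

    # species level: nested LMM on all species (tree-free)
    tt_all = traits_g.set_index("species").loc[species]
    X_lmm = np.column_stack(
        [np.ones(len(species)), sp_clim.loc[species, PREDICTORS].to_numpy(float)]
    )
    y_lmm = tt_all["log10_mass_g"].to_numpy(float)
    out["lmm_climate"] = fit_nested_lmm(
        y_lmm, X_lmm, tt_all["family"], tt_all["genus"],
        terms=["intercept"] + PREDICTORS,
    )
    filtered = drop_widest_ranging(
        traits_g, sp_clim["range_size"], cfg.range_filter_fraction
    )
    fsp = list(filtered["species"])
    if len(fsp) >= n_pred + 2:
        Xf = np.column_stack(
            [np.ones(len(fsp)), sp_clim.loc[fsp, PREDICTORS].to_numpy(float)]
        )
        ft = filtered.set_index("species").loc[fsp]
        out["lmm_climate_filtered"] = fit_nested_lmm(
            ft["log10_mass_g"].to_numpy(float), Xf, ft["family"], ft["genus"],
            terms=["intercept"] + PREDICTORS,
        )
    return out


def _lat_gradient_rows(results: dict) -> pd.DataFrame:
    """Latitudinal-gradient summary: one row per (level, group)."""
    rows = []
    for name, res in results.items():
        if res is None:
            continue
        f = res["sar_lat"]
        rows.append({
            "level": "assemblage", "group": name, "n": res["n_species"],
            "estimate": f.coef("lat"), "se": f.coef_se("lat"),
            "r2": f.extras["pseudo_r2"], "p": f.pvalue("lat"),
            "lambda": np.nan, "pattern": res["lat_pattern"],
        })
        if "pgls_lat" in res:
            g = res["pgls_lat"]
            rows.append({
                "level": "species", "group": name, "n": g.n,
                "estimate": g.coef("lat"), "se": g.coef_se("lat"),
                "r2": g.extras["r2"], "p": g.pvalue("lat"),
                "lambda": g.extras["lambda_pagel"],
                "pattern": res["pgls_lat_pattern"],
            })
    return pd.DataFrame(rows)


def _climate_fit_rows(results: dict) -> pd.DataFrame:
    """Multivariate-fit summary: coefficient +/- SE with stars per model."""
    rows = []
    for name, res in results.items():
        if res is None:
            continue
        for key, level in (
            ("sar_climate", "assemblage_sar"),
            ("pgls_climate", "species_pgls"),
            ("lmm_climate", "species_lmm"),
            ("lmm_climate_filtered", "species_lmm_rangefiltered"),
        ):
            if key not in res:
                continue
            fit = res[key]
            row = {"model": level, "group": name, "n": fit.n}
            row.update(fit.summary_row())
            if "pseudo_r2" in fit.extras:
                row["r2"] = fit.extras["pseudo_r2"]
            elif "r2" in fit.extras:
                row["r2"] = fit.extras["r2"]
            if "lambda_pagel" in fit.extras:
                row["lambda"] = fit.extras["lambda_pagel"]
            rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(cfg: AnalysisConfig, outdir=None, run_null: bool = True) -> dict:
    """Execute the whole pipeline; optionally write the report bundle.

    Returns a dict with per-group fit records, the two summary tables, the
    all-species gradient grid, and a manifest tying every output to
    (analysis level, group, model, seed).
    """
    data = get_dataset(cfg)
    groups = cfg.groups
    if groups is None:
        groups = {f: [f] for f in sorted(data.traits["family"].unique())}

    results: dict = {}
    results["all"] = analyze_group(
        "all", sorted(data.traits["species"]), data, cfg, seed=cfg.seed + 101,
        run_null=run_null,
    )
    skipped = []
    for gi, (name, fams) in enumerate(sorted(groups.items())):
        species = _group_species(data, fams)
        if not species:
            log.warning("group %s is empty; omitted from outputs", name)
            skipped.append(name)
            continue
        res = analyze_group(
            name, species, data, cfg, seed=cfg.seed + 201 + gi, run_null=run_null
        )
        if res is None:
            skipped.append(name)
        else:
            results[name] = res

    table_lat = _lat_gradient_rows(results)
    table_climate = _climate_fit_rows(results)
    gradient = results["all"]["assemblage_table"] if results["all"] else None

    import dendropy, scipy, statsmodels
    from importlib.metadata import version as _dist_version

    try:
        _pkg_version = _dist_version("sizeclines")
    except Exception:
        _pkg_version = "unknown"
    manifest = {
        "package_version": _pkg_version,
        "versions": {
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
            "dendropy": dendropy.__version__,
        },
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "groups": {k: (results[k]["n_species"] if k in results else "skipped")
                   for k in list(groups) + ["all"]},
        "skipped_groups": skipped,
        "analyses": sorted(
            {f"{g}:{k}" for g, r in results.items() if r
             for k in r if hasattr(r[k], "tidy")}
        ),
    }

    bundle = {
        "results": results,
        "table_latitude": table_lat,
        "table_climate": table_climate,
        "gradient": gradient,
        "manifest": manifest,
    }
    if outdir is not None:
        write_report(bundle, cfg, outdir)
    return bundle


def write_report(bundle: dict, cfg: AnalysisConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["table_latitude"].to_csv(outdir / "latitude_gradients.csv", index=False)
    bundle["table_climate"].to_csv(outdir / "climate_fits.csv", index=False)
    if bundle["gradient"] is not None:
        bundle["gradient"].to_csv(outdir / "gradient.csv", index=False)
    for name, res in bundle["results"].items():
        if res is None:
            continue
        for key, fit in res.items():
            if hasattr(fit, "tidy"):
                fit.write(outdir / f"{name}_{key}.csv", outdir / f"{name}_{key}.json")
        if "null" in res:
            res["null"].to_json(outdir / f"{name}_null.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
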