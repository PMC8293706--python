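"""Simulation studies: parameter recovery, null-model calibration, sign recovery.

These functions run the package end to end on synthetic data with known
truth and summarize how well the estimators recover it.  They are the
basis of the package's self-validation (and of the reproduction script in
``scripts/``); sizes default to values that run in a few minutes on one
CPU.

Study conditions are fixed here, not tunable per call site: climate noise
SDs are doubled relative to the surface defaults and the smoothing radius
is 1, so the five predictors remain well-conditioned at the study sample
sizes (heavily smoothed surfaces make all variables near-collinear
functions of latitude, which says nothing about the estimators).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .assemblage import species_climate_summary
from .grids import CLIMATE_VARS, GridSpec, generate_climate_grid, generate_ranges
from .nullmodel import null_reliability_test
from .pgls import fit_pgls
from .phylo import simulate_phylogeny, simulate_traits
from .pipeline import AnalysisConfig, run_full_analysis
from .sar import build_weights, fit_sar_error

#: independent climate variation used by every study (per-variable noise SD)
STUDY_NOISE_SD = {"MAT": 2.0, "TS": 50.0, "AP": 240.0, "PS": 8.0, "NPP": 180.0}
STUDY_SMOOTHING = 1

SAR_TRUTH = {
    "lambda_sp": 0.8,
    "beta": np.array([1.0, 0.02, 0.001, 2e-4, -0.01, 4e-4]),
    "sigma": 0.1,
}
PGLS_TRUTH = {
    "lambda": 0.9,
    "beta": np.array([1.0, 0.02, 0.0, 0.0, 0.0, 0.0]),
    "sigma_phylo": 0.2,
    "sigma_resid": 0.0,
}
LMM_TRUTH = {"var_family": 0.3, "var_genus": 0.2, "var_resid": 0.1}


def _child_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2^31 derived from a master seed."""
    return int(np.random.default_rng([seed, *tags]).integers(2**31))


def sar_parameter_recovery(
    n_reps: int = 100, n_rows: int = 20, n_cols: int = 20, seed: int = 0
) -> dict:
    """Spatial-error model on data simulated from its own model.

    Truth: lambda_sp = 0.8, sigma = 0.1, climate coefficients as in
    SAR_TRUTH, on a 20 x 20 grid (400 cells).  Returns the mean lambda_sp
    estimate and the relative bias of each climate coefficient.
    """
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols)
    W = build_weights(grid.cell_ids(), grid)
    lam_true = SAR_TRUTH["lambda_sp"]
    beta_true = SAR_TRUTH["beta"]
    I = np.eye(grid.n_cells)
    lams, betas = [], []
    for rep in range(n_reps):
        clim = generate_climate_grid(
            grid, noise_sd=STUDY_NOISE_SD, smoothing_radius=STUDY_SMOOTHING,
            seed=_child_seed(seed, 1, rep))
        X = np.column_stack(
            [np.ones(grid.n_cells)] + [clim.values[v] for v in CLIMATE_VARS])
        rng = np.random.default_rng(_child_seed(seed, 2, rep))
        u = np.linalg.solve(I - lam_true * W.W,
                            rng.normal(0.0, SAR_TRUTH["sigma"], grid.n_cells))
        fit = fit_sar_error(X @ beta_true + u, X, W,
                            ["intercept"] + list(CLIMATE_VARS))
        lams.append(fit.extras["lambda_sp"])
        betas.append(fit.beta)
    betas = np.asarray(betas)
    rel_bias = (betas.mean(axis=0)[1:] - beta_true[1:]) / beta_true[1:]
    return {
        "lambda_sp_mean": float(np.mean(lams)),
        "lambda_sp_true": lam_true,
        "beta_rel_bias": {v: float(b) for v, b in zip(CLIMATE_VARS, rel_bias)},
        "max_abs_beta_rel_bias": float(np.max(np.abs(rel_bias))),
        "n_reps": n_reps,
        "n_cells": grid.n_cells,
    }


def pgls_parameter_recovery(
    n_reps: int = 100, n_tips: int = 200, seed: int = 0
) -> dict:
    """PGLS on traits simulated under its own generative model.

    Truth: Pagel's lambda = 0.9, beta_MAT = 0.02, sigma_phylo = 0.2,
    sigma_resid = 0 (so the marginal trait covariance is exactly the
    lambda-transformed phylogenetic covariance the estimator fits).
    """
    grid = GridSpec(n_rows=20, n_cols=20)
    lams, bmat = [], []
    for rep in range(n_reps):
        clim = generate_climate_grid(
            grid, noise_sd=STUDY_NOISE_SD, smoothing_radius=STUDY_SMOOTHING,
            seed=_child_seed(seed, 3, rep))
        pam = generate_ranges(clim, n_tips, (5, 40),
                              seed=_child_seed(seed, 4, rep))
        tree = simulate_phylogeny(n_tips, seed=_child_seed(seed, 5, rep))
        spc = species_climate_summary(pam, clim)
        traits = simulate_traits(
            tree, spc, beta=PGLS_TRUTH["beta"],
            sigma_phylo=PGLS_TRUTH["sigma_phylo"],
            sigma_resid=PGLS_TRUTH["sigma_resid"],
            lambda_true=PGLS_TRUTH["lambda"],
            seed=_child_seed(seed, 6, rep))
        sp = sorted(traits["species"])
        X = np.column_stack(
            [np.ones(len(sp)), spc.loc[sp, list(CLIMATE_VARS)].to_numpy(float)])
        y = traits.set_index("species").loc[sp, "log10_mass_g"].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_pgls(y, X, tree, species=sp,
                           terms=["intercept"] + list(CLIMATE_VARS))
        lams.append(fit.extras["lambda_pagel"])
        bmat.append(fit.coef("MAT"))
    return {
        "lambda_pagel_mean": float(np.mean(lams)),
        "lambda_pagel_true": PGLS_TRUTH["lambda"],
        "beta_mat_mean": float(np.mean(bmat)),
        "beta_mat_true": float(PGLS_TRUTH["beta"][1]),
        "beta_mat_rel_bias": float(
            (np.mean(bmat) - PGLS_TRUTH["beta"][1]) / PGLS_TRUTH["beta"][1]),
        "n_reps": n_reps,
        "n_tips": n_tips,
    }


def lmm_component_recovery(n_reps: int = 100, seed: int = 0) -> dict:
    """Nested-LMM variance components on a balanced synthetic design.

    20 families x 5 genera x 4 species, true components
    (family, genus, residual) = (0.3, 0.2, 0.1), REML.
    """
    from .mixedmodel import fit_nested_lmm

    n_fam, n_gen, n_sp = 20, 5, 4
    n = n_fam * n_gen * n_sp
    fam = np.repeat([f"f{i:02d}" for i in range(n_fam)], n_gen * n_sp)
    gen = np.repeat([f"f{i:02d}g{j}" for i in range(n_fam) for j in range(n_gen)], n_sp)
    est = []
    for rep in range(n_reps):
        rng = np.random.default_rng(_child_seed(seed, 7, rep))
        x = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        bf = rng.normal(0, np.sqrt(LMM_TRUTH["var_family"]), n_fam)
        bg = rng.normal(0, np.sqrt(LMM_TRUTH["var_genus"]), n_fam * n_gen)
        y = (1.0 + 0.5 * x
             + np.repeat(bf, n_gen * n_sp) + np.repeat(bg, n_sp)
             + rng.normal(0, np.sqrt(LMM_TRUTH["var_resid"]), n))
        fit = fit_nested_lmm(y, X, fam, gen, terms=["intercept", "x"])
        est.append([fit.extras["var_family"], fit.extras["var_genus"],
                    fit.extras["var_resid"]])
    mean = np.asarray(est).mean(axis=0)
    truth = np.array([LMM_TRUTH["var_family"], LMM_TRUTH["var_genus"],
                      LMM_TRUTH["var_resid"]])
    return {
        "var_means": {k: float(v) for k, v in
                      zip(("family", "genus", "resid"), mean)},
        "var_rel_bias": {k: float(b) for k, b in
                         zip(("family", "genus", "resid"),
                             (mean - truth) / truth)},
        "max_abs_rel_bias": float(np.max(np.abs((mean - truth) / truth))),
        "n_reps": n_reps,
    }


def null_model_calibration(
    n_datasets: int = 100,
    n_rand: int = 50,
    effect: str = "none",
    seed: int = 0,
    n_rows: int = 12,
    n_cols: int = 12,
    n_species: int = 60,
) -> dict:
    """Fire rate of the reliability verdict over simulated datasets.

    ``effect="none"``: species masses are i.i.d. noise, so any verdict is a
    false alarm (type-I error).  ``effect="strong"``: masses track species
    mean annual temperature with little noise (power).  Both the t-test
    verdict (the classical decision rule) and the exact permutation verdict
    are counted.
    """
    if effect not in ("none", "strong"):
        raise ValueError(f"effect must be 'none' or 'strong', got {effect!r}")
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols)
    fires_t = fires_perm = 0
    for rep in range(n_datasets):
        clim = generate_climate_grid(
            grid, noise_sd=STUDY_NOISE_SD, smoothing_radius=STUDY_SMOOTHING,
            seed=_child_seed(seed, 8, rep))
        pam = generate_ranges(clim, n_species, (4, 20),
                              seed=_child_seed(seed, 9, rep))
        rng = np.random.default_rng(_child_seed(seed, 10, rep))
        spc = species_climate_summary(pam, clim)
        if effect == "none":
            mass = rng.normal(1.5, 0.3, n_species)
        else:
            mass = 1.0 + 0.08 * spc["MAT"].to_numpy() + rng.normal(0, 0.05, n_species)
        traits = pd.DataFrame({
            "species": pam.species, "family": "fam00", "genus": "fam00_gen00",
            "max_svl_mm": 100.0, "log10_mass_g": mass, "in_tree": True,
        })
        res = null_reliability_test(
            pam, traits, clim, n_rand=n_rand,
            seed=_child_seed(seed, 11, rep))
        fires_t += res.p < res.alpha
        fires_perm += res.p_permutation < res.alpha
    return {
        "effect": effect,
        "fire_rate_ttest": fires_t / n_datasets,
        "fire_rate_permutation": fires_perm / n_datasets,
        "n_datasets": n_datasets,
        "n_rand": n_rand,
    }


def sign_recovery_study(n_reps: int = 100, seed: int = 0) -> dict:
    """End-to-end orchestrated runs with opposite-sign temperature effects.

    Two families are simulated with beta_MAT = +0.1 and -0.1; a replicate
    counts as recovered when each family's fitted species-level (PGLS) MAT
    coefficient has the generating sign.  The assemblage-level (SAR) sign
    agreement is reported alongside: cell medians mix species across
    groups' range overlaps, so it is expected to be noisier.
    """
    ok_pgls = ok_sar = usable = 0
    for rep in range(n_reps):
        cfg = AnalysisConfig(
            simulation={
                "seed": _child_seed(seed, 12, rep),
                "n_rows": 18, "n_cols": 12, "n_species": 70,
                "range_size": (4, 16),
                "n_families": 2, "genera_per_family": 4,
                "noise_sd": STUDY_NOISE_SD,
                "smoothing_radius": STUDY_SMOOTHING,
                "beta": {"fam00": [1.0, 0.1, 0, 0, 0, 0],
                         "fam01": [1.0, -0.1, 0, 0, 0, 0]},
                "sigma_phylo": 0.08, "sigma_resid": 0.02, "lambda_true": 0.9,
            },
            n_rand=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = run_full_analysis(cfg, run_null=False)
        res = bundle["results"]
        if "fam00" not in res or "fam01" not in res:
            continue
        usable += 1
        p0 = res["fam00"]["pgls_climate"].coef("MAT")
        p1 = res["fam01"]["pgls_climate"].coef("MAT")
        s0 = res["fam00"]["sar_climate"].coef("MAT")
        s1 = res["fam01"]["sar_climate"].coef("MAT")
        ok_pgls += (p0 > 0) and (p1 < 0)
        ok_sar += (s0 > 0) and (s1 < 0)
    return {
        "pgls_sign_recovery_rate": ok_pgls / usable if usable else float("nan"),
        "sar_sign_recovery_rate": ok_sar / usable if usable else float("nan"),
        "n_reps": n_reps,
        "n_usable": usable,
    }
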