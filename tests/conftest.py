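import numpy as np
import pandas as pd
import pytest

import sizeclines as sc
from sizeclines.assemblage import species_climate_summary
from sizeclines.grids import GridSpec, PresenceAbsenceMatrix


@pytest.fixture(scope="session")
def toy_pam():
    """3 species on a 1x4 grid: A in cells {0,1}, B in {1}, C in {1,2}.

    Cell 3 is empty.  With masses 1, 2, 3 the cell medians are
    {0: 1.0, 1: 2.0, 2: 3.0}.
    """
    grid = GridSpec(n_rows=1, n_cols=4)
    mat = np.zeros((3, 4), dtype=bool)
    mat[0, [0, 1]] = True
    mat[1, [1]] = True
    mat[2, [1, 2]] = True
    return PresenceAbsenceMatrix(grid, ["A", "B", "C"], mat)


@pytest.fixture(scope="session")
def toy_traits():
    return pd.DataFrame(
        {
            "species": ["A", "B", "C"],
            "family": ["f1", "f1", "f2"],
            "genus": ["g1", "g2", "g3"],
            "max_svl_mm": [50.0, 80.0, 120.0],
            "log10_mass_g": [1.0, 2.0, 3.0],
            "in_tree": [True, True, True],
        }
    )


@pytest.fixture(scope="session")
def toy_climate(toy_pam):
    grid = toy_pam.grid
    vals = {
        "MAT": np.array([20.0, 18.0, 16.0, 14.0]),
        "TS": np.array([400.0, 420.0, 440.0, 460.0]),
        "AP": np.array([1500.0, 1300.0, 1100.0, 900.0]),
        "PS": np.array([50.0, 55.0, 60.0, 65.0]),
        "NPP": np.array([1000.0, 900.0, 800.0, 700.0]),
    }
    return sc.ClimateGrid(grid=grid, values=vals)


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated 12x12 landscape with 40 species, tree and traits."""
    grid = GridSpec(n_rows=12, n_cols=12)
    climate = sc.generate_climate_grid(grid, smoothing_radius=1, seed=11)
    pam = sc.generate_ranges(climate, 40, (4, 20), seed=12)
    tree = sc.simulate_phylogeny(40, seed=13)
    spc = species_climate_summary(pam, climate)
    traits = sc.simulate_traits(
        tree, spc, beta=[1.0, 0.03, 0, 0, 0, 0],
        sigma_phylo=0.2, sigma_resid=0.02, lambda_true=0.9, seed=14,
    )
    return {"grid": grid, "climate": climate, "pam": pam, "tree": tree,
            "species_climate": spc, "traits": traits}
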