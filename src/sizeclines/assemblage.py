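"""Assemblage construction: per-cell medians, climate, richness; and
per-species climate summaries for the species-level analyses.

The assemblage response is the *median* log10 body mass of all species
whose range overlaps a cell; medians with an even species count use the
mean of the two central values.  Species-level climate is the unweighted
mean of each variable over the species' occupied cells, and the species'
latitude is its range-centroid latitude — an explicit aggregation choice,
since occurrence data could equally be summarized at type localities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyAnalysisError, MissingSpeciesError
from .grids import CLIMATE_VARS, ClimateGrid, PresenceAbsenceMatrix

ASSEMBLAGE_COLUMNS = (
    "cell_id", "lat", "lon", "median_log10_mass", *CLIMATE_VARS, "richness",
)


def _mass_lookup(pam: PresenceAbsenceMatrix, traits: pd.DataFrame) -> np.ndarray:
    t = traits.set_index("species")
    missing = [s for s in pam.species if s not in t.index]
    if missing:
        raise MissingSpeciesError(f"species in ranges but not in traits: {missing}")
    return t.loc[pam.species, "log10_mass_g"].to_numpy(float)


def cell_median_mass(pam: PresenceAbsenceMatrix, traits: pd.DataFrame) -> pd.Series:
    """Median log10 mass over the species present in each occupied cell.

    Returns a Series indexed by cell_id, covering occupied cells only.
    """
    masses = _mass_lookup(pam, traits)
    occ = pam.matrix
    occupied = np.flatnonzero(occ.any(axis=0))
    med = np.array([np.median(masses[occ[:, c]]) for c in occupied])
    return pd.Series(med, index=pd.Index(occupied, name="cell_id"),
                     name="median_log10_mass")


def build_assemblage_table(
    pam: PresenceAbsenceMatrix,
    traits: pd.DataFrame,
    climate: ClimateGrid,
    min_richness: int = 1,
) -> pd.DataFrame:
    """One row per retained cell: median mass, mean climate, richness, centroid.

    Cells hosting fewer than ``min_richness`` species are dropped.  Climate
    enters as the cell value (the synthetic climate is generated at analysis
    resolution, so the within-cell mean is the cell value itself).
    """
    if pam.grid != climate.grid:
        raise EmptyAnalysisError("presence-absence and climate grids differ")
    med = cell_median_mass(pam, traits)
    richness = pam.richness[med.index.to_numpy()]
    keep = richness >= min_richness
    if not keep.any():
        raise EmptyAnalysisError(
            f"no cells with richness >= {min_richness} remain"
        )
    cells = med.index.to_numpy()[keep]
    lat, lon = climate.grid.cell_latlon(cells)
    out = pd.DataFrame({"cell_id": cells, "lat": lat, "lon": lon,
                        "median_log10_mass": med.to_numpy()[keep]})
    for var in CLIMATE_VARS:
        out[var] = climate.values[var][cells]
    out["richness"] = richness[keep]
    return out.reset_index(drop=True)


def species_climate_summary(
    pam: PresenceAbsenceMatrix, climate: ClimateGrid
) -> pd.DataFrame:
    """Unweighted climate means over each species' occupied cells.

    Returns a DataFrame indexed by species with the five climate columns,
    range-centroid latitude, and range size in cells.
    """
    if pam.grid != climate.grid:
        raise EmptyAnalysisError("presence-absence and climate grids differ")
    occ = pam.matrix.astype(float)
    sizes = occ.sum(axis=1)
    if np.any(sizes == 0):
        empty = [s for s, k in zip(pam.species, sizes) if k == 0]
        raise EmptyAnalysisError(f"species with empty ranges: {empty}")
    lat = climate.grid.latitudes()
    data = {"centroid_lat": occ @ lat / sizes}
    for var in CLIMATE_VARS:
        data[var] = occ @ climate.values[var] / sizes
    out = pd.DataFrame(data, index=pd.Index(pam.species, name="species"))
    out["range_size"] = sizes.astype(int)
    return out[["MAT", "TS", "AP", "PS", "NPP", "centroid_lat", "range_size"]]
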