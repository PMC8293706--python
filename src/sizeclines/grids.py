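"""Synthetic gridded landscapes: climate surfaces and virtual species ranges.

Cells live on a regular latitude-longitude grid (default 1 x 1 degree) and
are addressed by row-major integer ids; latitudes and longitudes always
refer to cell centers.  Climate surfaces combine a latitudinal trend with
spatially smoothed Gaussian noise; virtual ranges are grown by a
spreading-dye process (random contiguous accretion), optionally biased
toward cells climatically similar to the seed cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidGridError

#: Canonical order of the five climate predictors: mean annual temperature,
#: temperature seasonality, annual precipitation, precipitation seasonality,
#: net primary productivity.
CLIMATE_VARS = ("MAT", "TS", "AP", "PS", "NPP")

#: Default latitudinal trend per variable (change per degree latitude) and
#: the value at the southern grid edge.  Magnitudes emulate the climatic
#: span of subtropical-to-temperate East Asia: MAT in deg C, TS as an SD
#: index, AP in mm/yr, PS as a CV (%), NPP in g C m-2 yr-1.
DEFAULT_INTERCEPTS = {"MAT": 25.0, "TS": 400.0, "AP": 1800.0, "PS": 55.0, "NPP": 1200.0}
DEFAULT_SLOPES = {"MAT": -0.5, "TS": 15.0, "AP": -40.0, "PS": 0.5, "NPP": -25.0}
DEFAULT_NOISE_SD = {"MAT": 1.0, "TS": 25.0, "AP": 120.0, "PS": 4.0, "NPP": 90.0}


@dataclass(frozen=True)
class GridSpec:
    """A regular lat-lon grid; rows index latitude, columns longitude."""

    n_rows: int
    n_cols: int
    lat_min: float = 18.0
    lon_min: float = 75.0
    resolution: float = 1.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidGridError(
                f"grid dimensions must be positive, got {self.n_rows} x {self.n_cols}"
            )
        if self.resolution <= 0:
            raise InvalidGridError(f"resolution must be positive, got {self.resolution}")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.resolution

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.resolution

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells, dtype=int)

    def rowcol(self, cell_id: np.ndarray | int):
        """Row-major id -> (row, col)."""
        return np.divmod(cell_id, self.n_cols)

    def cell_latlon(self, cell_id: np.ndarray | int):
        """Cell-center coordinates for row-major ids."""
        row, col = self.rowcol(np.asarray(cell_id))
        lat = self.lat_min + (row + 0.5) * self.resolution
        lon = self.lon_min + (col + 0.5) * self.resolution
        return lat, lon

    def latitudes(self) -> np.ndarray:
        return self.cell_latlon(self.cell_ids())[0]

    def longitudes(self) -> np.ndarray:
        return self.cell_latlon(self.cell_ids())[1]

    def neighbors4(self, cell_id: int) -> list[int]:
        """Rook (4-connected) neighbor ids of a cell."""
        r, c = divmod(cell_id, self.n_cols)
        out = []
        if r > 0:
            out.append(cell_id - self.n_cols)
        if r < self.n_rows - 1:
            out.append(cell_id + self.n_cols)
        if c > 0:
            out.append(cell_id - 1)
        if c < self.n_cols - 1:
            out.append(cell_id + 1)
        return out


@dataclass
class ClimateGrid:
    """Per-cell values for the five climate variables on a GridSpec."""

    grid: GridSpec
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for var, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.n_cells,):
                raise InvalidGridError(
                    f"variable {var!r} has shape {arr.shape}, expected ({self.grid.n_cells},)"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidGridError(f"variable {var!r} contains non-finite values")
            self.values[var] = arr

    def to_frame(self) -> pd.DataFrame:
        lat, lon = self.grid.cell_latlon(self.grid.cell_ids())
        df = pd.DataFrame({"cell_id": self.grid.cell_ids(), "lat": lat, "lon": lon})
        for var in self.values:
            df[var] = self.values[var]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, grid: GridSpec) -> "ClimateGrid":
        df = pd.read_csv(path).sort_values("cell_id")
        if len(df) != grid.n_cells:
            raise InvalidGridError(
                f"climate CSV has {len(df)} rows, grid has {grid.n_cells} cells"
            )
        vals = {v: df[v].to_numpy(float) for v in df.columns if v in CLIMATE_VARS}
        return cls(grid=grid, values=vals)


@dataclass
class PresenceAbsenceMatrix:
    """Species x cell boolean occupancy; the bridge from ranges to assemblages."""

    grid: GridSpec
    species: list[str]
    matrix: np.ndarray  # bool, shape (n_species, n_cells)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.species), self.grid.n_cells):
            raise InvalidGridError(
                f"occupancy matrix shape {self.matrix.shape} does not match "
                f"{len(self.species)} species x {self.grid.n_cells} cells"
            )

    @property
    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species (row sums)."""
        return self.matrix.sum(axis=1)

    @property
    def richness(self) -> np.ndarray:
        """Species count per cell (column sums)."""
        return self.matrix.sum(axis=0)

    def subset_species(self, keep: list[str]) -> "PresenceAbsenceMatrix":
        idx = [self.species.index(s) for s in keep]
        return PresenceAbsenceMatrix(self.grid, list(keep), self.matrix[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix.astype(int), index=self.species, columns=self.grid.cell_ids()
        )
        df.index.name = "species"
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path, grid: GridSpec) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, index_col="species")
        mat = np.zeros((len(df), grid.n_cells), dtype=bool)
        cols = df.columns.astype(int).to_numpy()
        mat[:, cols] = df.to_numpy() > 0
        return cls(grid, list(df.index), mat)


def _smooth(field2d: np.ndarray, radius: int) -> np.ndarray:
    """Moving-average smoothing over a (2r+1)^2 window, truncated and
    renormalized at grid edges so edge cells average only real neighbors."""
    if radius == 0:
        return field2d
    size = 2 * radius + 1
    num = ndimage.uniform_filter(field2d, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(field2d), size=size, mode="constant", cval=0.0)
    return num / den


def generate_climate_grid(
    spec: GridSpec,
    trend_slopes: dict[str, float] | None = None,
    intercepts: dict[str, float] | None = None,
    noise_sd: dict[str, float] | float | None = None,
    smoothing_radius: int = 2,
    seed: int = 0,
) -> ClimateGrid:
    """Latitudinal trend plus spatially smoothed Gaussian noise, per variable.

    Each variable is ``intercept + slope * (lat - lat_min) + noise`` where the
    intercept is the expected value at the southern grid edge and the noise is
    white Gaussian noise (SD ``noise_sd``) smoothed by a moving average of the
    given radius.  Smoothing shrinks the marginal noise variance; the
    ``noise_sd`` parameter is the SD *before* smoothing.  Identical seeds give
    identical grids.
    """
    slopes = dict(DEFAULT_SLOPES)
    if trend_slopes:
        slopes.update(trend_slopes)
    icepts = dict(DEFAULT_INTERCEPTS)
    if intercepts:
        icepts.update(intercepts)
    if noise_sd is None:
        sds = dict(DEFAULT_NOISE_SD)
    elif np.isscalar(noise_sd):
        sds = {v: float(noise_sd) for v in CLIMATE_VARS}
    else:
        sds = dict(DEFAULT_NOISE_SD)
        sds.update(noise_sd)
    for v, sd in sds.items():
        if sd < 0:
            raise ValueError(f"noise_sd for {v!r} must be >= 0, got {sd}")
    if smoothing_radius < 0:
        raise ValueError(f"smoothing_radius must be >= 0, got {smoothing_radius}")

    rng = np.random.default_rng(seed)
    lat = spec.latitudes()
    values = {}
    for var in CLIMATE_VARS:
        trend = icepts[var] + slopes[var] * (lat - spec.lat_min)
        noise = rng.normal(0.0, sds[var], size=(spec.n_rows, spec.n_cols))
        noise = _smooth(noise, smoothing_radius) if sds[var] > 0 else noise
        values[var] = trend + noise.ravel()
    return ClimateGrid(grid=spec, values=values)


def generate_ranges(
    climate: ClimateGrid,
    n_species: int,
    range_size_distribution: tuple[int, int] = (5, 60),
    niche_breadth: dict[str, float] | str | None = "none",
    seed: int = 0,
) -> PresenceAbsenceMatrix:
    """Grow contiguous virtual ranges by spreading-dye accretion.

    Each species starts from a uniformly random seed cell and repeatedly
    annexes a random unoccupied rook neighbor of its current range until the
    target size (drawn uniformly from ``range_size_distribution``) is reached.
    With a ``niche_breadth`` mapping (variable -> tolerance), candidate cells
    are weighted by a Gaussian kernel of their climatic distance to the seed
    cell, which concentrates ranges along the climate gradient; ``"none"``
    gives unweighted (spatially neutral) growth.
    """
    spec = climate.grid
    lo, hi = range_size_distribution
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid range size bounds ({lo}, {hi})")
    if hi > spec.n_cells:
        raise ValueError(
            f"max range size {hi} exceeds the {spec.n_cells}-cell grid"
        )
    if n_species == 0:
        warnings.warn("n_species=0: returning an empty presence-absence matrix")
        return PresenceAbsenceMatrix(spec, [], np.zeros((0, spec.n_cells), dtype=bool))

    weighted = not (niche_breadth is None or niche_breadth == "none")
    if weighted:
        clim = np.column_stack(
            [climate.values[v] / niche_breadth[v] for v in niche_breadth]
        )

    rng = np.random.default_rng(seed)
    mat = np.zeros((n_species, spec.n_cells), dtype=bool)
    for i in range(n_species):
        target = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(spec.n_cells))
        occupied = {start}
        frontier = set(spec.neighbors4(start)) - occupied
        while len(occupied) < target:
            if not frontier:
                warnings.warn(
                    f"species {i}: grid exhausted at {len(occupied)} of "
                    f"{target} cells; range truncated"
                )
                break
            cand = sorted(frontier)
            if weighted:
                d2 = ((clim[cand] - clim[start]) ** 2).sum(axis=1)
                w = np.exp(-0.5 * d2)
                tot = w.sum()
                w = w / tot if tot > 0 else np.full(len(cand), 1.0 / len(cand))
                pick = int(rng.choice(len(cand), p=w))
            else:
                pick = int(rng.integers(len(cand)))
            cell = cand[pick]
            occupied.add(cell)
            frontier.discard(cell)
            frontier.update(n for n in spec.neighbors4(cell) if n not in occupied)
        mat[i, list(occupied)] = True

    species = [f"sp{i:04d}" for i in range(n_species)]
    return PresenceAbsenceMatrix(spec, species, mat)
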