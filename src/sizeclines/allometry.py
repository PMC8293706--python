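"""Clade-specific length-mass allometry for lizards.

Body length (maximum snout-vent length, SVL, in mm) is converted to body
mass on the log10-gram scale with a power law fitted per clade:

    log10(mass g) = a + b * log10(SVL mm)

Because body plans differ strongly between clades (legless skinks vs
stocky agamids), the intercept ``a`` and slope ``b`` are clade-specific.
Default coefficients ship in an editable YAML config and are
literature-derived placeholders; every analysis also accepts precomputed
log10 mass directly, so exact coefficients are never required.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .errors import AllometryError


@dataclass(frozen=True)
class AllometryCoefficients:
    """Power-law coefficients for one clade: log10(mass g) = a + b*log10(SVL mm)."""

    clade: str
    a: float  # intercept, log10 grams
    b: float  # slope, dimensionless

    def __post_init__(self):
        if self.b <= 0:
            raise AllometryError(
                f"allometric slope must be positive for {self.clade!r}, got {self.b}"
            )


def svl_to_mass(svl_mm: float | np.ndarray, coeffs: AllometryCoefficients):
    """log10 body mass (g) from snout-vent length (mm)."""
    svl_mm = np.asarray(svl_mm, dtype=float)
    if np.any(svl_mm <= 0):
        raise AllometryError(f"SVL must be positive, got {svl_mm}")
    out = coeffs.a + coeffs.b * np.log10(svl_mm)
    return float(out) if out.ndim == 0 else out


def mass_to_svl(log10_mass_g: float | np.ndarray, coeffs: AllometryCoefficients):
    """Snout-vent length (mm) from log10 body mass (g); inverse of svl_to_mass."""
    if coeffs.b == 0:
        raise AllometryError(f"degenerate allometry (b=0) for {coeffs.clade!r}")
    log10_mass_g = np.asarray(log10_mass_g, dtype=float)
    out = 10.0 ** ((log10_mass_g - coeffs.a) / coeffs.b)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=8)
def load_allometry(path=None) -> dict[str, AllometryCoefficients]:
    """Load a clade -> {a, b} mapping from YAML (default: bundled config)."""
    if path is None:
        text = resources.files("sizeclines.data").joinpath("allometry.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        clade: AllometryCoefficients(clade=clade, a=float(v["a"]), b=float(v["b"]))
        for clade, v in raw.items()
    }


def coefficients_for(clade: str, table: dict[str, AllometryCoefficients]) -> AllometryCoefficients:
    """Look up a clade, falling back to the 'default' entry if present."""
    if clade in table:
        return table[clade]
    if "default" in table:
        return table["default"]
    raise AllometryError(f"no allometric coefficients for clade {clade!r}")
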