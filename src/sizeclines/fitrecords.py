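"""Shared fitted-model record: tidy coefficient table + JSON sidecar.

All model fits in the package (OLS, spatial-error SAR, PGLS, nested LMM)
serialize the same way: a tidy CSV with one row per term (term, estimate,
se, stat, p) and a JSON sidecar with scalar fit metadata (log-likelihood,
autocorrelation parameter, pseudo-R-squared, n).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def stars(p: float) -> str:
    """Significance stars at the .05 / .01 / .001 conventions."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class FitRecord:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    loglik: float
    n: int
    stat_name: str = "z"
    extras: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.pvalues[self.terms.index(term)])

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": np.asarray(self.beta, float),
                "se": np.asarray(self.se, float),
                self.stat_name: np.asarray(self.stat, float),
                "p": np.asarray(self.pvalues, float),
            }
        )

    def summary_row(self) -> dict:
        """Coefficient +/- SE with significance stars, one dict per fit."""
        out = {}
        for t, b, s, p in zip(self.terms, self.beta, self.se, self.pvalues):
            if t == "intercept":
                continue
            out[t] = f"{b:.3g} ± {s:.2g} {stars(p)}"
        return out

    def sidecar(self) -> dict:
        def _plain(v):
            if isinstance(v, (bool, str)):
                return v
            if isinstance(v, (int, np.integer)):
                return int(v)
            if np.isscalar(v):
                return float(v)
            return v

        side = {"loglik": float(self.loglik), "n": int(self.n)}
        side.update({k: _plain(v) for k, v in self.extras.items()})
        return side

    def write(self, csv_path, json_path=None) -> None:
        self.tidy().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.sidecar(), fh, indent=2, default=float)
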