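"""Spatial-error simultaneous autoregressive (SAR) models on grid assemblages.

The model is

    y = X beta + u,    u = lambda_sp * W u + eps,    eps ~ N(0, sigma^2 I)

with W a (row-standardized) contiguity matrix among retained grid cells.
Writing A = I - lambda_sp W, the log-likelihood is

    ll = -n/2 log(2 pi sigma^2) + log|A| - ||A (y - X beta)||^2 / (2 sigma^2)

For fixed lambda_sp, beta is the OLS solution on the whitened data
(A y, A X) and sigma^2 = RSS/n, so the likelihood is profiled down to a
one-dimensional search over lambda_sp.  log|A| = sum log(1 - lambda_sp w_i)
over the eigenvalues w_i of W, computed once per weights matrix; the
admissible interval for lambda_sp is (1/min w, 1/max w).

Goodness of fit is reported as the Nagelkerke pseudo-R-squared
1 - exp(-(2/n)(ll_model - ll_null)) against the intercept-only OLS null,
the index reported by the spatial-regression software family this model
class comes from; it is not a variance-explained proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import RankDeficiencyError
from .fitrecords import FitRecord
from .grids import GridSpec

_LAMBDA_MARGIN = 1e-6  # keep the search strictly inside the admissible interval
_LAMBDA_XATOL = 1e-8


@dataclass
class SpatialWeights:
    """Neighbor weights among retained cells, optionally row-standardized."""

    cell_ids: np.ndarray
    W: np.ndarray
    scheme: str = "queen"
    standardized: bool = True
    _eigs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (cached).  A row-standardized contiguity
        matrix is similar to a symmetric matrix, so its spectrum is real."""
        if self._eigs is None:
            self._eigs = np.sort(np.linalg.eigvals(self.W).real)
        return self._eigs

    def lambda_interval(self) -> tuple[float, float]:
        eigs = self.eigenvalues
        lo = 1.0 / eigs[0] if eigs[0] < 0 else -0.9999
        hi = 1.0 / eigs[-1] if eigs[-1] > 0 else 0.9999
        return lo, hi


def build_weights(
    cells: pd.DataFrame | np.ndarray,
    grid: GridSpec,
    scheme: str = "queen",
    standardize: bool = True,
) -> SpatialWeights:
    """Contiguity weights among retained cells on the analysis grid.

    ``scheme="queen"`` joins cells sharing an edge or a corner,
    ``"rook"`` an edge only.  Rows are standardized to sum to one; cells
    without any retained neighbor keep an all-zero row.
    """
    if scheme not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    ids = np.asarray(cells["cell_id"] if isinstance(cells, pd.DataFrame) else cells,
                     dtype=int)
    rows, cols = grid.rowcol(ids)
    pos = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    n = len(ids)
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    W = np.zeros((n, n))
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None:
                W[i, j] = 1.0
    if n == 1 or not W.any():
        warnings.warn("weights matrix has no neighbors; SAR reduces to OLS")
    if standardize:
        rowsum = W.sum(axis=1, keepdims=True)
        np.divide(W, rowsum, out=W, where=rowsum > 0)
    return SpatialWeights(cell_ids=ids, W=W, scheme=scheme, standardized=standardize)


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns beyond the numerical rank via pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, mode="economic", pivoting=True)
        bad = sorted(terms[j] for j in piv[rank:])
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear columns: {bad}"
        )


def gaussian_loglik(resid: np.ndarray, log_jacobian: float = 0.0) -> float:
    """Profiled Gaussian log-likelihood at the MLE sigma^2 = RSS/n.

    A perfect fit (RSS = 0) degenerates to +inf, which is the correct
    supremum of the likelihood."""
    n = len(resid)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0.0:
        return np.inf
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + log_jacobian


def fit_ols(y: np.ndarray, X: np.ndarray, terms: list[str] | None = None) -> FitRecord:
    """Ordinary least squares with ML Gaussian log-likelihood.

    Serves both as the non-spatial baseline and as the intercept-only null
    for the Nagelkerke pseudo-R-squared.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if n <= p:
        raise RankDeficiencyError(f"n={n} observations for p={p} parameters")
    _check_rank(X, terms)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    ll = gaussian_loglik(resid)
    sigma2_unb = rss / (n - p)
    cov = sigma2_unb * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(t), df=n - p)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return FitRecord(
        terms=list(terms), beta=beta, se=se, stat=t, pvalues=pvals,
        loglik=ll, n=n, stat_name="t",
        extras={"sigma2": rss / n, "r2": r2},
    )


def sar_error_loglik(
    lam: float, y: np.ndarray, X: np.ndarray, W: SpatialWeights,
    _cache: dict | None = None,
) -> float:
    """Profiled spatial-error log-likelihood at a given lambda_sp.

    beta and sigma^2 are concentrated out in closed form on the whitened
    data (I - lam W) y, (I - lam W) X.
    """
    if _cache is None:
        _cache = {"Wy": W.W @ y, "WX": W.W @ X}
    yt = y - lam * _cache["Wy"]
    Xt = X - lam * _cache["WX"]
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    logdet = float(np.sum(np.log(1.0 - lam * W.eigenvalues)))
    return gaussian_loglik(resid, log_jacobian=logdet)


def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    W: SpatialWeights,
    terms: list[str] | None = None,
    lambda_mode: str | float = "ml",
) -> FitRecord:
    """ML spatial-error SAR fit with profiled lambda_sp.

    ``lambda_mode="ml"`` profiles the likelihood over the admissible
    interval; a float fixes lambda_sp (0.0 reduces the model to OLS).
    Returns a FitRecord whose extras carry lambda_sp, sigma2, the
    intercept-only null log-likelihood, the Nagelkerke pseudo-R-squared and
    a boundary flag.  Coefficient p-values are two-sided asymptotic z tests
    with SEs from sigma^2 (X' A'A X)^{-1} at the optimum.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if W.n != n:
        raise ValueError(f"weights have {W.n} cells but data have {n} rows")
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if n <= p:
        raise RankDeficiencyError(f"n={n} observations for p={p} parameters")
    _check_rank(X, terms)

    cache = {"Wy": W.W @ y, "WX": W.W @ X}
    boundary = False
    if lambda_mode != "ml":
        lam_hat = float(lambda_mode)
    elif not W.W.any():  # isolated cells only: the model is plain OLS
        lam_hat = 0.0
    else:
        lo, hi = W.lambda_interval()
        lo += _LAMBDA_MARGIN
        hi -= _LAMBDA_MARGIN
        res = optimize.minimize_scalar(
            lambda lam: -sar_error_loglik(lam, y, X, W, cache),
            bounds=(lo, hi), method="bounded",
            options={"xatol": _LAMBDA_XATOL},
        )
        lam_hat = float(res.x)
        if min(lam_hat - lo, hi - lam_hat) < 1e-4:
            boundary = True
            warnings.warn(
                f"lambda_sp = {lam_hat:.6f} is at the boundary of its "
                f"admissible interval ({lo:.4f}, {hi:.4f})"
            )

    yt = y - lam_hat * cache["Wy"]
    Xt = X - lam_hat * cache["WX"]
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ resid) / n
    logdet = float(np.sum(np.log(1.0 - lam_hat * W.eigenvalues)))
    ll = gaussian_loglik(resid, log_jacobian=logdet)
    cov = sigma2 * np.linalg.inv(Xt.T @ Xt)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.norm.sf(np.abs(z))

    ll_null = fit_ols(y, np.ones((n, 1)), ["intercept"]).loglik
    r2 = nagelkerke_r2(ll, ll_null, n)
    return FitRecord(
        terms=list(terms), beta=beta, se=se, stat=z, pvalues=pvals,
        loglik=ll, n=n, stat_name="z",
        extras={
            "lambda_sp": lam_hat, "sigma2": sigma2, "loglik_null": ll_null,
            "pseudo_r2": r2, "boundary": boundary,
        },
    )


def nagelkerke_r2(
    loglik_model: float, loglik_null: float, n: int, normalized: bool = False
) -> float:
    """Likelihood-ratio pseudo-R-squared, 1 - exp(-(2/n) (ll_model - ll_null)).

    ``normalized=True`` divides by the maximum attainable value
    1 - exp((2/n) ll_null) (only meaningful when the null likelihood is a
    proper probability, i.e. <= 0).  Values are clamped to [0, 1).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    delta = loglik_model - loglik_null
    if delta < 0:
        warnings.warn(
            f"model log-likelihood {loglik_model:.4f} below null "
            f"{loglik_null:.4f}; pseudo-R2 clamped to 0"
        )
        return 0.0
    r2 = 1.0 - np.exp(-2.0 * delta / n)
    if normalized:
        r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
        if r2_max > 0:
            r2 = r2 / r2_max
    return float(min(r2, np.nextafter(1.0, 0.0)))


def classify_latitudinal_pattern(
    fit: FitRecord, alpha: float = 0.05, term: str = "lat"
) -> str:
    """Bergmann / inverse-Bergmann / none from a mass-on-latitude fit.

    A significant positive latitude slope (size increases poleward) is
    Bergmann's rule; a significant negative slope the inverse cline; a
    non-significant slope is classified as no pattern.
    """
    slope = fit.coef(term)
    p = fit.pvalue(term)
    if p < alpha:
        return "bergmann" if slope > 0 else "inverse_bergmann"
    return "none"


def design_matrix(
    table: pd.DataFrame, predictors: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response and intercept-first design from an assemblage/species table."""
    y = table["median_log10_mass" if "median_log10_mass" in table else
              "log10_mass_g"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[p].to_numpy(float) for p in predictors]
    )
    return y, X, ["intercept"] + list(predictors)
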