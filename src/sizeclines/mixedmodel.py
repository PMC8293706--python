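"""Taxonomically nested linear mixed models and the wide-range filter.

The tree-free species-level analysis: log10 mass regressed on climate
with random intercepts for family and for genus nested within family,

    y = X beta + b_family + b_genus:family + eps

With a single record per species, a species-level random term is not
identifiable and is absorbed into the residual.  The response is
continuous, so the model is a Gaussian LMM (identity link); fitting is
delegated to statsmodels' MixedLM with REML by default (ML by flag for
likelihood comparisons).

``drop_widest_ranging`` implements the sensitivity filter that removes
the 10% of species with the largest geographic ranges before refitting,
guarding against within-range climate averaging in wide-ranging species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import NestingViolationError, RankDeficiencyError
from .fitrecords import FitRecord


@dataclass
class LMMFit(FitRecord):
    pass


def _check_nesting(family: pd.Series, genus: pd.Series) -> None:
    fams_per_genus = pd.DataFrame({"family": family, "genus": genus}).groupby(
        "genus"
    )["family"].nunique()
    bad = fams_per_genus[fams_per_genus > 1]
    if len(bad):
        raise NestingViolationError(
            f"genera under more than one family: {sorted(bad.index)}"
        )


def fit_nested_lmm(
    y: np.ndarray,
    X: np.ndarray,
    family: pd.Series | np.ndarray,
    genus: pd.Series | np.ndarray,
    terms: list[str] | None = None,
    method: str = "reml",
) -> LMMFit:
    """Gaussian LMM with family and genus-within-family random intercepts.

    ``X`` must include an intercept column.  Fixed-effect inference uses
    asymptotic z tests; variance components (family, genus-within-family,
    residual) are reported in the extras.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"method must be 'reml' or 'ml', got {method!r}")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    family = pd.Series(np.asarray(family), name="family").astype(str)
    genus = pd.Series(np.asarray(genus), name="genus").astype(str)
    _check_nesting(family, genus)
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("fixed-effects design is rank deficient")
    if (genus.groupby(genus).size() == 1).all():
        warnings.warn(
            "all genera are singletons; the genus variance component is "
            "unidentifiable and will sit at the 0 boundary"
        )

    # standardize non-constant columns for the optimizer; transform back after.
    # the map is exact (affine equivariance), not an approximation.
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    const = scales <= 0
    means[const] = 0.0
    scales[const] = 1.0
    X_std = (X - means) / scales

    df = pd.DataFrame(X_std, columns=terms)
    df["_y"] = y
    df["family"] = family.to_numpy()
    df["genus"] = genus.to_numpy()
    rhs = " + ".join(f"Q('{t}')" for t in terms)
    n_fam = df["family"].nunique()
    n_gen = df["genus"].nunique()

    if n_fam == 1 and n_gen == 1:
        # no grouping structure left: degenerate to OLS with zero components
        warnings.warn("single family and genus; variance components fixed at 0")
        from .sar import fit_ols

        ols = fit_ols(y, X, terms)
        ols.extras = {"var_family": 0.0, "var_genus": 0.0,
                      "var_resid": ols.extras["sigma2"], "method": method,
                      "converged": True}
        return LMMFit(**{k: getattr(ols, k) for k in
                         ("terms", "beta", "se", "stat", "pvalues", "loglik",
                          "n", "stat_name", "extras")})

    if n_fam == 1:
        # the family intercept is unidentifiable against the fixed intercept;
        # keep the genus-within-family component only
        model = sm.MixedLM.from_formula(
            f"_y ~ 0 + {rhs}", data=df, groups="genus", re_formula="1")
    else:
        model = sm.MixedLM.from_formula(
            f"_y ~ 0 + {rhs}", data=df, groups="family", re_formula="1",
            vc_formula={"genus": "0 + C(genus)"})
    # lbfgs can step into singular covariance territory on small groups;
    # fall back to the slower derivative-free optimizers when it does
    result = None
    for opt in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # boundary/convergence chatter
                result = model.fit(reml=(method == "reml"), method=opt)
            break
        except np.linalg.LinAlgError:
            continue
    if result is None:
        raise np.linalg.LinAlgError("mixed-model optimization failed to converge")

    p = X.shape[1]
    beta_std = np.asarray(result.fe_params, float)
    cov_std = np.asarray(result.cov_params(), float)[:p, :p]
    # undo the standardization: b_j = b'_j / s_j, with the subtracted means
    # folded back into the (all-ones) intercept column
    M = np.diag(1.0 / scales)
    i0 = int(np.flatnonzero(const)[0]) if const.any() else None
    if i0 is not None:
        for j in range(p):
            if j != i0 and not const[j]:
                M[i0, j] = -means[j] / scales[j]
    beta = M @ beta_std
    cov = M @ cov_std @ M.T
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.norm.sf(np.abs(z))
    if n_fam == 1:
        var_family = 0.0
        var_genus = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    else:
        var_family = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
        var_genus = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    return LMMFit(
        terms=list(terms), beta=beta, se=se, stat=z, pvalues=pvals,
        loglik=float(result.llf), n=n, stat_name="z",
        extras={
            "var_family": var_family,
            "var_genus": var_genus,
            "var_resid": float(result.scale),
            "method": method,
            "converged": bool(result.converged),
        },
    )


def drop_widest_ranging(
    traits: pd.DataFrame,
    range_sizes: pd.Series,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Remove the ceil(fraction * n) species with the largest ranges.

    Ties at the cutoff are broken deterministically by retaining the
    lexicographically smallest species ids.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n = len(traits)
    k = math.ceil(fraction * n)
    if k == 0:
        return traits.copy()
    sizes = pd.Series(range_sizes).reindex(traits["species"])
    order = sorted(
        traits["species"], key=lambda s: (-sizes.loc[s], _reverse_key(s))
    )
    removed = set(order[:k])
    return traits[~traits["species"].isin(removed)].reset_index(drop=True)


def _reverse_key(s: str):
    """Sort key that orders strings in reverse lexicographic order, so the
    lexicographically largest ids among ties are removed first."""
    return tuple(-ord(c) for c in s)
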