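"""Redundancy analysis (RDA) of clr-ASV responses on environmental predictors.

RDA is the constrained ordination equivalent to (1) a multivariate OLS of the
column-centered response matrix Y on the predictors X, (2) a PCA of the
fitted values (constrained axes) and (3) a PCA of the residuals
(unconstrained axes). Scores are reported in scaling 1 ("distance scaling"):
site scores preserve inter-sample Euclidean distances and species scores are
unit eigenvector loadings. Axis signs are fixed by forcing the
largest-magnitude species loading on each axis to be positive.

A quadratic trend surface of an external index (here the SBI) over the first
two constrained axes supports contour rendering on the triplot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SingularDesignError

__all__ = ["RdaResult", "fit_rda", "project_index"]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class RdaResult:
    """Eigenvalues and scaling-1 scores of a redundancy analysis."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    site_scores: pd.DataFrame       # samples x constrained axes, preserves distances
    species_scores: pd.DataFrame    # features x constrained axes, unit loadings
    biplot_scores: pd.DataFrame     # predictors x constrained axes, correlations
    total_variance: float

    @property
    def proportion_constrained(self) -> float:
        """Share of total response variance captured by the constrained axes."""
        return float(self.constrained_eigenvalues.sum() / self.total_variance)


def _sign_fix(loadings: np.ndarray) -> np.ndarray:
    """Per-axis sign so the largest-|loading| species is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def fit_rda(Y: pd.DataFrame, X: pd.DataFrame) -> RdaResult:
    """Fit an RDA of responses ``Y`` (samples x features) on predictors ``X``.

    ``Y`` columns are centered internally; ``X`` should be standardized
    (an intercept is implicit via centering). Number of constrained axes is
    min(rank(X), n-1, n_features).
    """
    if not Y.index.equals(X.index):
        raise ValueError("Y and X sample ids differ or are ordered differently")
    n, m = Y.shape
    Yc = Y.to_numpy(dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise SingularDesignError("predictor matrix is rank deficient")

    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    resid = Yc - fitted

    # PCA of fitted values via SVD: eigenvalues of the fitted covariance
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    lam = s**2 / (n - 1)
    k = int(min(rank, np.sum(lam > _EIG_TOL * max(lam.max(), 1.0))))
    u, s, vt, lam = u[:, :k], s[:k], vt[:k], lam[:k]

    signs = _sign_fix(vt.T)
    species = vt.T * signs                 # unit eigenvectors (scaling 1)
    sites = u * s * signs                  # distance-preserving site scores

    _, s_res, _ = np.linalg.svd(resid, full_matrices=False)
    lam_res = s_res**2 / (n - 1)
    lam_res = lam_res[lam_res > _EIG_TOL * max(lam_res.max(), 1.0) if lam_res.size else 0]

    axes = [f"RDA{i + 1}" for i in range(k)]
    with np.errstate(invalid="ignore"):
        biplot = np.corrcoef(Xc, sites, rowvar=False)[: Xc.shape[1], Xc.shape[1]:]
    return RdaResult(
        constrained_eigenvalues=lam,
        unconstrained_eigenvalues=lam_res,
        site_scores=pd.DataFrame(sites, index=Y.index, columns=axes),
        species_scores=pd.DataFrame(species, index=Y.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=X.columns, columns=axes),
        total_variance=float((Yc**2).sum() / (n - 1)),
    )


def project_index(result: RdaResult, index_values: pd.Series,
                  grid_size: int = 50) -> pd.DataFrame:
    """Quadratic trend surface of an index over the first two constrained axes.

    Fits z ~ 1 + a1 + a2 + a1^2 + a1*a2 + a2^2 by least squares on the site
    scores and evaluates it on a regular grid spanning the score range.

    Returns a long-format frame with columns ``axis1``, ``axis2``, ``value``
    plus the fitted in-sample surface values as attribute ``fitted_at_sites``
    (a Series aligned to samples) and the linear-gradient vector as attribute
    ``gradient``.
    """
    sites = result.site_scores
    if sites.shape[0] < 10:
        raise InsufficientDataError("need at least 10 samples for a trend surface")
    if sites.shape[1] < 2:
        raise InsufficientDataError("need at least 2 constrained axes")
    if not index_values.index.equals(sites.index):
        raise ValueError("index values misaligned with site scores")

    a1 = sites.iloc[:, 0].to_numpy()
    a2 = sites.iloc[:, 1].to_numpy()
    z = index_values.to_numpy(dtype=float)

    def design(x1, x2):
        return np.column_stack([np.ones_like(x1), x1, x2, x1**2, x1 * x2, x2**2])

    coef, *_ = np.linalg.lstsq(design(a1, a2), z, rcond=None)

    g1 = np.linspace(a1.min(), a1.max(), grid_size)
    g2 = np.linspace(a2.min(), a2.max(), grid_size)
    G1, G2 = np.meshgrid(g1, g2)
    surface = design(G1.ravel(), G2.ravel()) @ coef
    out = pd.DataFrame({"axis1": G1.ravel(), "axis2": G2.ravel(), "value": surface})
    out.attrs["fitted_at_sites"] = pd.Series(design(a1, a2) @ coef, index=sites.index,
                                             name="fitted_index")
    out.attrs["gradient"] = coef[1:3].copy()
    out.attrs["coefficients"] = coef
    return out
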