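"""Linear mixed model machinery for haplotype scans.

The model is ``y = X c + g + e`` with polygenic effect
``g ~ N(0, sigma_g^2 K)`` and noise ``e ~ N(0, sigma_e^2 I)``. Writing
``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`` and rotating into the
eigenbasis of K (``K = U diag(lam) U'``) turns the covariance into the
diagonal ``w_i = h2 lam_i + (1 - h2)``, so for fixed h2 every fit is a
weighted least squares. The null heritability is estimated by restricted
maximum likelihood (REML) with a coarse grid on [0, 0.99] followed by
bounded 1-D refinement; per-marker LOD scores then compare weighted
residual sums of squares at that fixed h2 (EMMAX-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import qr

from .errors import DataError

__all__ = ["NullFit", "fit_null", "check_full_rank", "wls_rss"]

H2_MAX = 0.99


@dataclass
class NullFit:
    """Result of the covariates-only REML fit."""

    h2: float
    loglik: float
    weights: np.ndarray          # w_i = h2*lam_i + (1-h2)
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray | None  # None when no kinship (identity rotation)
    rss0: float                  # weighted RSS of the covariates-only model
    unidentifiable: bool = False


def check_full_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise a :class:`DataError` naming collinear columns if X is rank-deficient."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank == p:
        return
    _, _, piv = qr(X, mode="economic", pivoting=True)
    bad = sorted(piv[rank:])
    labels = [names[j] if names else f"column {j}" for j in bad]
    raise DataError(f"covariate design is rank-deficient; collinear columns: {labels}")


def wls_rss(Xw: np.ndarray, yw: np.ndarray) -> float:
    """Residual sum of squares of a (pre-weighted) least-squares fit.

    Rank-deficient designs are handled by the minimum-norm solution, so a
    duplicated column never changes the RSS.
    """
    beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
    r = yw - Xw @ beta
    return float(r @ r)


def _reml_neg_loglik(h2: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    n, p = Xr.shape
    w = h2 * lam + (1.0 - h2)
    sw = 1.0 / np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    rss = wls_rss(Xw, yw)
    if rss <= 0:
        return np.inf
    sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * rss / (n - p)) + 1.0)
        + np.sum(np.log(w))
        + logdet_xx
    )
    return -ll


def fit_null(
    y: np.ndarray,
    X: np.ndarray,
    eigen: tuple[np.ndarray, np.ndarray] | None,
    names: list[str] | None = None,
    n_grid: int = 101,
    tol: float = 1e-6,
) -> NullFit:
    """REML fit of the covariates-only mixed model.

    ``eigen`` is the (eigenvalues, eigenvectors) pair of the kinship
    matrix, or ``None`` for no random effect (h2 fixed at 0). When the
    kinship is (numerically) the identity the model collapses — h2 is
    unidentifiable — and the fit returns h2=0 with a flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise DataError(f"y has {y.shape[0]} rows but X has {X.shape[0]}")
    if not np.all(np.isfinite(y)):
        raise DataError("missing values in y must be dropped before the null fit")
    if not np.all(np.isfinite(X)):
        raise DataError("covariate rows must be complete")
    check_full_rank(X, names)
    n, p = X.shape

    if eigen is None:
        rss0 = wls_rss(X, y)
        return NullFit(
            h2=0.0,
            loglik=-_reml_neg_loglik(0.0, np.ones(n), y, X),
            weights=np.ones(n),
            eigenvalues=np.ones(n),
            eigenvectors=None,
            rss0=rss0,
        )

    lam, U = eigen
    if np.ptp(lam) < 1e-8:
        # identity-like kinship: the variance split is unidentifiable
        yr = U.T @ y
        Xr = U.T @ X
        return NullFit(
            h2=0.0,
            loglik=-_reml_neg_loglik(0.0, lam, yr, Xr),
            weights=np.ones(n),
            eigenvalues=lam,
            eigenvectors=U,
            rss0=wls_rss(Xr, yr),
            unidentifiable=True,
        )

    yr = U.T @ y
    Xr = U.T @ X
    grid = np.linspace(0.0, H2_MAX, n_grid)
    vals = np.array([_reml_neg_loglik(h, lam, yr, Xr) for h in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(lam, yr, Xr),
        method="bounded",
        options={"xatol": tol},
    )
    h2 = float(res.x) if res.fun <= vals[k] else float(grid[k])
    nll = min(float(res.fun), float(vals[k]))
    w = h2 * lam + (1.0 - h2)
    sw = 1.0 / np.sqrt(w)
    rss0 = wls_rss(Xr * sw[:, None], yr * sw)
    return NullFit(
        h2=h2,
        loglik=-nll,
        weights=w,
        eigenvalues=lam,
        eigenvectors=U,
        rss0=rss0,
    )
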