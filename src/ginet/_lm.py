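"""Small internal least-squares helpers shared by the statistical modules.

All model fitting in this package reduces to ordinary least squares with
Wald-type inference on one coefficient; these helpers keep that in one
place (QR-based, multi-response capable) so the scan can solve one design
against many target genes at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class OLSFit:
    coef: np.ndarray  # (p,) or (p, k)
    se: np.ndarray
    rss: np.ndarray  # scalar-like or (k,)
    dof: int
    rank: int


def add_intercept(*blocks: np.ndarray) -> np.ndarray:
    """Stack an intercept column with any number of 1-D/2-D blocks."""
    n = None
    cols = []
    for b in blocks:
        if b is None:
            continue
        b = np.asarray(b, dtype=float)
        if b.ndim == 1:
            b = b[:, None]
        if b.shape[1] == 0:
            continue
        n = b.shape[0] if n is None else n
        cols.append(b)
    if n is None:
        raise ValueError("no design columns")
    return np.column_stack([np.ones(n)] + cols)


def ols(X: np.ndarray, Y: np.ndarray, check_rank: bool = True,
        column_names: list[str] | None = None) -> OLSFit:
    """OLS of Y (n,) or (n, k) on X (n, p); classical standard errors.

    Perfect fits (zero residual variance) get se = 0; callers interpret
    a zero coefficient with zero se as "no effect, p = 1".
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if check_rank and rank < p:
        bad = sorted(piv[rank:].tolist())
        names = (
            [column_names[i] for i in bad] if column_names is not None else bad
        )
        raise CollinearityError(f"rank-deficient design; collinear columns: {names}")
    coef_piv = linalg.solve_triangular(R[:rank, :rank], (Q.T @ Y)[:rank])
    coef = np.zeros((p,) + Y.shape[1:])
    coef[piv[:rank]] = coef_piv
    resid = Y - X @ coef
    rss = np.sum(resid**2, axis=0)
    dof = n - rank
    # (X'X)^-1 diagonal via R inverse on the pivoted block
    Rinv = linalg.solve_triangular(R[:rank, :rank], np.eye(rank))
    xtx_inv_diag = np.full(p, np.nan)
    xtx_inv_diag[piv[:rank]] = np.sum(Rinv**2, axis=1)
    sigma2 = rss / dof if dof > 0 else rss * np.nan
    # guard: treat numerically perfect fits as exact
    yss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    perfect = rss <= 1e-12 * np.maximum(yss, 1.0)
    sigma2 = np.where(perfect, 0.0, sigma2)
    if np.ndim(sigma2) == 0:
        se = np.sqrt(sigma2 * xtx_inv_diag)
    else:
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    return OLSFit(coef=coef, se=se, rss=rss, dof=dof, rank=rank)


def wald_z(coef: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal-theory Wald test; (0, se=0) maps to z=0, p=1."""
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return z, p


def t_pvalue(coef: np.ndarray, se: np.ndarray, dof: int) -> np.ndarray:
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    return np.clip(2.0 * stats.t.sf(np.abs(t), dof), np.finfo(float).tiny, 1.0)


def residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of Y on [1, C] (least-norm solution, tolerant of collinear C)."""
    Y = np.asarray(Y, dtype=float)
    X = add_intercept(C) if C is not None and np.size(C) else np.ones((Y.shape[0], 1))
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta
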