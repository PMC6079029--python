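"""Latent-covariate estimation from expression data.

Unknown covariates (batch effects, cell-composition shifts not captured by
measured counts, technical structure) are estimated as the leading
sample-space singular directions of the expression matrix after
residualizing every gene on the known covariates. The factors are used
only as additional unpenalized covariates downstream, so any deterministic
basis spanning the confounder subspace serves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lm import residualize
from .core_io import CovariateSet, DataError, ExpressionMatrix


@dataclass
class LatentFactors:
    samples: list[str]
    factors: np.ndarray  # samples x k, standardized columns
    k: int

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float).reshape(
            len(self.samples), -1
        )
        if self.factors.shape[1] != self.k:
            raise DataError("factor matrix width != k")


def estimate_latent_factors(
    expr: ExpressionMatrix, known: CovariateSet, k: int = 5
) -> LatentFactors:
    """Top-k residual singular directions as latent covariates.

    Each gene is residualized on the known covariates (intercept, cohort,
    sex, age, cell counts where available); the returned factors are the
    leading left singular vectors of the residual samples x genes matrix,
    standardized to unit variance, with the sign fixed so each factor's
    largest-magnitude entry is positive.
    """
    if expr.samples != known.samples:
        raise DataError("expression and covariates have different samples")
    n = len(expr.samples)
    if k <= 0:
        return LatentFactors(samples=list(expr.samples), factors=np.empty((n, 0)), k=0)
    if k >= n:
        raise DataError(f"k={k} must be smaller than the number of samples ({n})")
    C, _ = known.design(include_latent=False)
    R = residualize(expr.values.T, C)  # samples x genes
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    k_eff = min(k, int(np.sum(s > s.max() * 1e-10)) if s.size else 0)
    if k_eff < k:
        raise DataError(
            f"residual matrix supports only {k_eff} factors; requested {k}"
        )
    F = U[:, :k]
    # deterministic sign: largest-magnitude entry of each factor positive
    flip = np.sign(F[np.argmax(np.abs(F), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    F = F * flip
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    return LatentFactors(samples=list(expr.samples), factors=F, k=k)
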