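"""Sobel mediation test of GI -> index expression -> target expression.

If an index gene truly mediates its GI's effect on a target, the GI ->
target effect should run through observed index expression: path *a* is
the GI's effect on index expression, path *b* the index expression's
effect on the target adjusted for the GI; the indirect effect a*b is
tested with Sobel's normal-theory statistic
z = a*b / sqrt(a^2 se_b^2 + b^2 se_a^2). Both path regressions adjust for
the covariates and neighbouring GIs, mirroring the scan model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._lm import add_intercept, ols
from .core_io import CovariateSet, DataError


@dataclass(frozen=True)
class MediationResult:
    index_gene: str
    target_gene: str
    a: float
    se_a: float
    b: float
    se_b: float
    sobel_z: float
    p: float


def sobel_test(
    gi_values: np.ndarray,
    index_expr: np.ndarray,
    target_expr: np.ndarray,
    cov: CovariateSet | None = None,
    neighbour_values: np.ndarray | None = None,
    index_gene: str = "",
    target_gene: str = "",
) -> MediationResult:
    """Sobel test for mediation of the GI effect by index expression."""
    gi = np.asarray(gi_values, dtype=float)
    m = np.asarray(index_expr, dtype=float)
    y = np.asarray(target_expr, dtype=float)
    if m.std() == 0:
        raise DataError("zero-variance mediator")
    C = cov.design()[0] if cov is not None else None
    G = None
    if neighbour_values is not None and np.size(neighbour_values):
        G = np.asarray(neighbour_values, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
    fit_a = ols(add_intercept(gi, C, G) if C is not None or G is not None
                else add_intercept(gi), m, check_rank=False)
    a, se_a = float(fit_a.coef[1]), float(fit_a.se[1])
    Xb = add_intercept(m, gi, C, G)
    fit_b = ols(Xb, y, check_rank=False)
    b, se_b = float(fit_b.coef[1]), float(fit_b.se[1])
    z, p = sobel_statistic(a, se_a, b, se_b)
    return MediationResult(
        index_gene=index_gene,
        target_gene=target_gene,
        a=a,
        se_a=se_a,
        b=b,
        se_b=se_b,
        sobel_z=z,
        p=p,
    )


def sobel_statistic(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Classic Sobel z and two-sided normal p from the two path estimates."""
    denom = math.sqrt(a * a * se_b * se_b + b * b * se_a * se_a)
    if denom == 0.0:
        return 0.0, 1.0
    z = a * b / denom
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return float(z), max(p, float(np.finfo(float).tiny))
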