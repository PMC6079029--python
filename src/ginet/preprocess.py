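"""Variant QC, expression normalization, and covariate completion.

Variant QC removes SNPs with minor allele frequency < 0.01, a
Hardy-Weinberg exact-test P < 1e-4, or a call rate below 95% (computed on
dosages rounded to hard genotypes). Expression is library-size normalized
to counts per million, genes are kept when their median log(CPM) exceeds 0
(equivalently median CPM > 1), and values are mapped to normal quantiles by
a rank-based inverse normal transformation within each cohort. Missing red
and white blood cell counts are imputed from expression principal
components plus the demographic covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from ._lm import add_intercept
from .core_io import CovariateSet, DataError, ExpressionMatrix, GenotypeData


@dataclass(frozen=True)
class QCReport:
    n_input_variants: int
    n_fail_maf: int
    n_fail_hwe: int
    n_fail_callrate: int
    n_pass: int

    def __post_init__(self):
        total = self.n_pass + self.n_fail_maf + self.n_fail_hwe + self.n_fail_callrate
        if total != self.n_input_variants:
            raise DataError("QC counts do not sum to input variant count")


@lru_cache(maxsize=100_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (mid-less convention, as in the standard SNP-HWE exact test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("all genotype counts are zero")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice moot
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # heterozygote count must share parity with the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a constant
    from scipy.special import gammaln

    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    ll = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    ll -= ll.max()
    probs = np.exp(ll)
    probs /= probs.sum()
    obs = probs[hets == n_Aa]
    if obs.size == 0:  # impossible configuration given allele counts
        raise DataError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def variant_qc(
    geno: GenotypeData,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-4,
    call_rate_min: float = 0.95,
) -> tuple[GenotypeData, QCReport]:
    """Filter variants on MAF, HWE and call rate.

    MAF is computed from the mean non-missing dosage / 2, folded to <= 0.5.
    HWE and call rate use dosages rounded to the nearest hard genotype.
    A variant failing several rules is counted once, under the first
    failing rule in the order MAF, HWE, call rate.
    """
    if geno.n_samples == 0:
        raise DataError("genotype data has zero samples")
    D = geno.dosage
    n = geno.n_samples
    keep = np.ones(geno.n_variants, dtype=bool)
    n_maf = n_hwe = n_call = 0
    for j in range(geno.n_variants):
        d = D[:, j]
        obs = np.isfinite(d)
        if not obs.any():
            n_call += 1
            keep[j] = False
            continue
        af = d[obs].mean() / 2.0
        maf = min(af, 1.0 - af)
        g = np.rint(d[obs]).astype(int)
        if maf < maf_min:
            n_maf += 1
            keep[j] = False
            continue
        counts = np.bincount(g, minlength=3)
        if hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) < hwe_alpha:
            n_hwe += 1
            keep[j] = False
            continue
        if obs.sum() / n < call_rate_min:
            n_call += 1
            keep[j] = False
    report = QCReport(
        n_input_variants=geno.n_variants,
        n_fail_maf=n_maf,
        n_fail_hwe=n_hwe,
        n_fail_callrate=n_call,
        n_pass=int(keep.sum()),
    )
    return geno.subset_variants(keep), report


def cpm_and_filter(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """CPM-normalize and keep genes with median CPM > 1 (strict).

    Returns the kept genes on the natural-log CPM scale. The filter is
    log-base free: median log(CPM) > 0 iff median CPM > 1.
    """
    if counts.scale != "counts":
        raise DataError(f"expected counts scale, got {counts.scale}")
    libsize = counts.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise DataError(
            f"zero library size for sample(s): {[counts.samples[i] for i in zero]}"
        )
    cpm = counts.values / libsize * 1e6
    kept_mask = np.median(cpm, axis=1) > 1.0
    kept = [g for g, k in zip(counts.genes, kept_mask) if k]
    with np.errstate(divide="ignore"):
        logcpm = np.log(cpm[kept_mask, :])
    return (
        ExpressionMatrix(
            genes=kept, samples=list(counts.samples), values=logcpm, scale="logcpm"
        ),
        kept,
    )


def rank_inverse_normal(
    values: np.ndarray, groups: np.ndarray | None = None, c: float = 3.0 / 8.0
) -> np.ndarray:
    """Rank-based inverse normal transform within groups (Blom offset).

    value -> Phi^-1((rank - c) / (n - 2c + 1)) within each group; ties get
    mid-ranks. Raises for constant values within a group.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        v = values[sel]
        if len(v) < 2:
            raise DataError(f"group {g!r} has fewer than 2 members")
        if np.all(v == v[0]):
            raise DataError(f"constant values within group {g!r}")
        ranks = stats.rankdata(v, method="average")
        out[sel] = stats.norm.ppf((ranks - c) / (len(v) - 2 * c + 1))
    return out


def transform_expression(
    expr: ExpressionMatrix, cohorts: np.ndarray
) -> ExpressionMatrix:
    """Apply the within-cohort inverse normal transform to every gene."""
    vals = np.vstack(
        [rank_inverse_normal(expr.values[i, :], cohorts) for i in range(len(expr.genes))]
    ) if len(expr.genes) else expr.values.copy()
    return ExpressionMatrix(
        genes=list(expr.genes),
        samples=list(expr.samples),
        values=vals,
        scale="int-transformed",
    )


def impute_cell_counts(
    cov: CovariateSet,
    expr: ExpressionMatrix,
    n_components: int = 10,
    min_observed_frac: float = 0.5,
) -> CovariateSet:
    """Fill missing RBC/WBC from expression principal components.

    Missing entries are predicted by least squares from the top
    ``n_components`` PCs of the (transformed) expression matrix plus
    cohort, sex and age; observed entries are untouched and stay flagged
    as observed.
    """
    if cov.samples != expr.samples:
        raise DataError("covariates and expression have different samples")
    out = {}
    needs = {}
    for name in ("rbc", "wbc"):
        v = getattr(cov, name)
        if v is None:
            continue
        miss = ~np.isfinite(v)
        if miss.any():
            frac_obs = 1.0 - miss.mean()
            if frac_obs < min_observed_frac:
                raise DataError(
                    f"only {frac_obs:.0%} of {name} observed; need >= "
                    f"{min_observed_frac:.0%}"
                )
            needs[name] = miss
        out[name] = v.copy()
    if not needs:
        return cov

    X = expr.values.T  # samples x genes
    Xc = X - X.mean(axis=0)
    k = min(n_components, min(Xc.shape) - 1)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :k] * s[:k]
    base, _ = CovariateSet(
        samples=cov.samples, cohort=cov.cohort, sex=cov.sex, age=cov.age
    ).design()
    design = add_intercept(pcs, base)
    for name, miss in needs.items():
        v = out[name]
        obs = ~miss
        beta, *_ = np.linalg.lstsq(design[obs], v[obs], rcond=None)
        v[miss] = design[miss] @ beta
        out[name] = v
    return CovariateSet(
        samples=list(cov.samples),
        cohort=cov.cohort,
        sex=cov.sex,
        age=cov.age,
        rbc=out.get("rbc"),
        wbc=out.get("wbc"),
        latent=cov.latent,
        rbc_observed=(
            np.isfinite(cov.rbc) if cov.rbc is not None else None
        ),
        wbc_observed=(
            np.isfinite(cov.wbc) if cov.wbc is not None else None
        ),
    )
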