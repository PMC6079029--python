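"""Per-gene genetic instruments for expression.

A genetic instrument (GI) for gene *j* is a sparse weighted sum of
standardized cis-SNP dosages predicting *j*'s expression. Weights come
from an L1-penalized regression fitted on a training third of the samples
with known and latent covariates left unpenalized; the penalty is chosen
by seeded, cohort-stratified cross-validation at minimum mean squared
error. Instrument strength is then evaluated on the held-out test set as
the ANOVA F-statistic for the GI's added predictive power over covariates
and the GIs of neighbouring genes (< 1 Mb); instruments with F <= 10 are
discarded as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import sklearn
from sklearn.linear_model import Lasso, LassoCV

from ._lm import add_intercept, ols, residualize
from .core_io import CovariateSet, DataError, GeneAnnotation, GenotypeData, gene_distance

log = logging.getLogger(__name__)


@dataclass
class SampleSplit:
    train: list[str]
    test: list[str]
    seed: int

    def __post_init__(self):
        if set(self.train) & set(self.test):
            raise DataError("train and test sets overlap")


@dataclass
class GeneticInstrument:
    """Sparse SNP weights on the standardized-dosage scale, with the
    training-set standardization statistics frozen for later scoring."""

    gene_id: str
    weights: dict[str, float]
    variant_means: dict[str, float]
    variant_sds: dict[str, float]
    lambda_: float
    n_train: int

    def __post_init__(self):
        self.weights = {v: w for v, w in self.weights.items() if w != 0.0}
        if not self.weights:
            raise DataError(f"instrument for {self.gene_id} has no nonzero weight")
        missing = set(self.weights) - set(self.variant_means)
        if missing or set(self.weights) - set(self.variant_sds):
            raise DataError("weighted variants missing standardization stats")


@dataclass(frozen=True)
class InstrumentStrength:
    gene_id: str
    f_statistic: float
    df_num: int
    df_den: int
    keep: bool


def split_samples(
    cov: CovariateSet, train_frac: float = 1.0 / 3.0, seed: int = 0
) -> SampleSplit:
    """Stratified systematic train/test split.

    Within each cohort x sex stratum, samples are sorted by age and every
    ``round(1/train_frac)``-th sample (seeded per-stratum offset) goes to
    the training set, balancing cohort, sex and age across the split.
    """
    if not (0.0 < train_frac < 1.0):
        raise DataError(f"train_frac must be in (0, 1), got {train_frac}")
    step = max(2, int(round(1.0 / train_frac)))
    rng = np.random.default_rng(seed)
    samples = np.asarray(cov.samples)
    train: list[str] = []
    test: list[str] = []
    strata = sorted(
        set(zip(cov.cohort.tolist(), cov.sex.tolist())), key=lambda t: tuple(map(str, t))
    )
    for coh, sex in strata:
        sel = np.flatnonzero((cov.cohort == coh) & (cov.sex == sex))
        order = sel[np.lexsort((samples[sel], cov.age[sel]))]
        offset = int(rng.integers(step))
        for i, idx in enumerate(order):
            (train if i % step == offset else test).append(samples[idx])
    return SampleSplit(train=train, test=test, seed=seed)


def cis_window(gene: GeneAnnotation, flank: int = 100_000) -> tuple[str, int, int]:
    """Cis region: gene body extended by ``flank`` bp each side, floored at 1.

    Equals the union of the gene body with the TSS- and TES-centred flanks.
    """
    return gene.chrom, max(1, gene.start - flank), gene.end + flank


def _cv_folds(
    samples: list[str], cohort: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cohort-stratified, seeded K-fold assignment.

    Fold membership is keyed on sample IDs (within-cohort ID order), so the
    same sample set yields the same folds regardless of row order.
    """
    rng = np.random.default_rng(seed)
    samples = np.asarray(samples)
    n = len(samples)
    assign = np.empty(n, dtype=int)
    for coh in sorted(set(cohort.tolist()), key=str):
        idx = np.flatnonzero(cohort == coh)
        idx = idx[np.argsort(samples[idx])]
        labels = rng.permutation(np.arange(len(idx)) % n_folds)
        assign[idx] = labels
    folds = []
    for f in range(n_folds):
        folds.append((np.flatnonzero(assign != f), np.flatnonzero(assign == f)))
    return folds


def fit_instrument(
    gene: GeneAnnotation,
    geno_cis: GenotypeData,
    expr_train: np.ndarray,
    cov_train: CovariateSet,
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 1e-3,
    forced_alpha: float | None = None,
) -> GeneticInstrument | None:
    """L1-penalized cis model with unpenalized covariates.

    Dosages are standardized using training means/sds (missing dosages
    imputed at the mean). Because the covariates are unpenalized, the SNP
    coefficients solve the lasso of covariate-residualized expression on
    covariate-residualized standardized dosages (Frisch-Waugh-Lovell); the
    penalty grid is 100 log-spaced values descending from the smallest
    penalty that zeroes every SNP coefficient, and the final penalty
    minimizes cross-validated error. Returns ``None`` when no SNP weight
    survives.
    """
    if geno_cis.n_variants < 1:
        return None
    y = np.asarray(expr_train, dtype=float)
    n = len(y)
    if geno_cis.n_samples != n or cov_train.n_samples != n:
        raise DataError("train samples inconsistent across inputs")
    C, _ = cov_train.design()
    if n <= C.shape[1] + 1:
        raise DataError("fewer training samples than covariates")

    D = geno_cis.dosage.copy()
    means = np.nanmean(D, axis=0)
    sds = np.nanstd(D, axis=0)
    usable = sds > 0
    if not usable.any():
        return None
    D = D[:, usable]
    means_u, sds_u = means[usable], sds[usable]
    ids = [v.id for v, u in zip(geno_cis.variants, usable) if u]
    # standardize with missing -> mean (0 after scaling)
    Z = (D - means_u) / sds_u
    Z[~np.isfinite(Z)] = 0.0

    yr = residualize(y, C)
    Zr = residualize(Z, C)
    alpha_max = np.max(np.abs(Zr.T @ yr)) / n
    if alpha_max <= 0:
        return None
    alphas = np.logspace(
        np.log10(alpha_max), np.log10(alpha_max * alpha_min_ratio), n_alphas
    )
    # inputs are validated above; skip sklearn's per-call revalidation,
    # which dominates runtime on genome-wide fits
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        if forced_alpha is not None:
            best_alpha = float(forced_alpha)
        else:
            cv = _cv_folds(cov_train.samples, cov_train.cohort, cv_folds, seed)
            model = LassoCV(
                alphas=alphas, cv=cv, fit_intercept=False, max_iter=10_000, tol=1e-6
            )
            model.fit(Zr, yr)
            best_alpha = float(model.alpha_)
        fit = Lasso(alpha=best_alpha, fit_intercept=False, max_iter=10_000, tol=1e-8)
        fit.fit(Zr, yr)
    nz = np.flatnonzero(fit.coef_)
    if nz.size == 0:
        return None
    return GeneticInstrument(
        gene_id=gene.gene_id,
        weights={ids[i]: float(fit.coef_[i]) for i in nz},
        variant_means={ids[i]: float(means_u[i]) for i in nz},
        variant_sds={ids[i]: float(sds_u[i]) for i in nz},
        lambda_=best_alpha,
        n_train=n,
    )


def score_instrument(gi: GeneticInstrument, geno: GenotypeData) -> np.ndarray:
    """GI values: weighted sum of standardized dosages (training stats)."""
    idx = geno.variant_index()
    missing = [v for v in gi.weights if v not in idx]
    if missing:
        raise DataError(
            f"instrument {gi.gene_id}: weighted variant(s) absent from genotypes: "
            f"{missing}"
        )
    out = np.zeros(geno.n_samples)
    for vid, w in gi.weights.items():
        z = (geno.dosage[:, idx[vid]] - gi.variant_means[vid]) / gi.variant_sds[vid]
        z = np.where(np.isfinite(z), z, 0.0)
        out += w * z
    return out


def neighbour_instruments(
    gene: GeneAnnotation,
    instruments: dict[str, GeneticInstrument],
    annotations: dict[str, GeneAnnotation],
    radius: int = 1_000_000,
) -> list[GeneticInstrument]:
    """Instruments of other genes with gene-boundary distance < radius
    (same chromosome; overlapping genes count as distance 0)."""
    out = []
    for gid in sorted(instruments):
        if gid == gene.gene_id or gid not in annotations:
            continue
        if gene_distance(gene, annotations[gid]) < radius:
            out.append(instruments[gid])
    return out


def instrument_strength(
    gi_values: np.ndarray,
    expr_test: np.ndarray,
    cov_test: CovariateSet,
    neighbour_values: np.ndarray | None = None,
    threshold: float = 10.0,
    gene_id: str = "",
) -> InstrumentStrength:
    """Added-predictive-power ANOVA F of the GI on the held-out samples.

    Compares covariates + neighbour GIs against the same model plus the
    index GI: F = ((RSS_reduced - RSS_full)/1) / (RSS_full/(n - p_full)).
    ``keep`` is True iff F strictly exceeds ``threshold``.
    """
    gi_values = np.asarray(gi_values, dtype=float)
    if gi_values.std() == 0:
        raise DataError("constant GI vector; F undefined")
    y = np.asarray(expr_test, dtype=float)
    C, _ = cov_test.design()
    G = None
    if neighbour_values is not None and np.size(neighbour_values):
        G = np.asarray(neighbour_values, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
    X_red = add_intercept(C, G) if G is not None else add_intercept(C)
    X_full = np.column_stack([X_red, gi_values])
    fit_red = ols(X_red, y, check_rank=False)
    fit_full = ols(X_full, y, check_rank=False)
    df_den = len(y) - fit_full.rank
    if df_den <= 0:
        raise DataError("no residual degrees of freedom in full model")
    num = max(0.0, float(fit_red.rss - fit_full.rss))
    f = (num / 1.0) / (float(fit_full.rss) / df_den) if fit_full.rss > 0 else (
        0.0 if num == 0.0 else float("inf")
    )
    return InstrumentStrength(
        gene_id=gene_id,
        f_statistic=f,
        df_num=1,
        df_den=df_den,
        keep=bool(f > threshold),
    )


def fit_all_instruments(
    annotations: list[GeneAnnotation],
    geno: GenotypeData,
    expr,
    cov: CovariateSet,
    split: SampleSplit,
    flank: int = 100_000,
    cv_folds: int = 5,
    seed: int = 0,
) -> dict[str, GeneticInstrument]:
    """Fit a cis instrument for every annotated gene present in ``expr``
    using the training samples; genes with no cis variant or no surviving
    weight are skipped (logged)."""
    geno_train = geno.subset_samples(split.train)
    expr_train = expr.subset_samples(split.train)
    cov_train = cov.subset(split.train)
    gidx = expr_train.gene_index()
    out: dict[str, GeneticInstrument] = {}
    n_no_cis = 0
    for gene in annotations:
        if gene.gene_id not in gidx:
            continue
        chrom, lo, hi = cis_window(gene, flank)
        cis = geno_train.in_region(chrom, lo, hi)
        if cis.n_variants == 0:
            n_no_cis += 1
            continue
        gi = fit_instrument(
            gene,
            cis,
            expr_train.values[gidx[gene.gene_id]],
            cov_train,
            cv_folds=cv_folds,
            seed=seed,
        )
        if gi is not None:
            out[gene.gene_id] = gi
    if n_no_cis:
        log.info("%d genes had no cis variant after QC", n_no_cis)
    log.info("fitted instruments for %d genes", len(out))
    return out


def evaluate_instruments(
    instruments: dict[str, GeneticInstrument],
    annotations: list[GeneAnnotation],
    geno: GenotypeData,
    expr,
    cov: CovariateSet,
    split: SampleSplit,
    radius: int = 1_000_000,
    threshold: float = 10.0,
) -> dict[str, InstrumentStrength]:
    """Test-set conditional F-statistics for all fitted instruments."""
    ann = {g.gene_id: g for g in annotations}
    geno_test = geno.subset_samples(split.test)
    expr_test = expr.subset_samples(split.test)
    cov_test = cov.subset(split.test)
    gidx = expr_test.gene_index()
    gi_test = {g: score_instrument(gi, geno_test) for g, gi in instruments.items()}
    out: dict[str, InstrumentStrength] = {}
    for gid, gi in instruments.items():
        neigh = neighbour_instruments(ann[gid], instruments, ann, radius)
        G = (
            np.column_stack([gi_test[x.gene_id] for x in neigh])
            if neigh
            else None
        )
        out[gid] = instrument_strength(
            gi_test[gid],
            expr_test.values[gidx[gid]],
            cov_test,
            G,
            threshold=threshold,
            gene_id=gid,
        )
    return out
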