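"""Synthetic multi-cohort genotype + expression data with known truth.

Emulates the statistical structure the pipeline assumes: LD-blocked
biallelic dosages, expression with a sparse cis-genetic architecture,
shared latent confounders, blood-cell-count effects, local pleiotropy
(one variant carrying cis weights for two neighbouring genes), and
injected trans edges (index gene -> distal target gene). Every generated
dataset ships with a :class:`SyntheticTruth` so recovery can be checked
edge by edge.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import (
    CovariateSet,
    DataError,
    ExpressionMatrix,
    GeneAnnotation,
    GenotypeData,
    VariantRecord,
    gene_distance,
    write_annotation_table,
    write_covariate_table,
    write_dosage_vcf,
    write_expression_table,
)
from .instruments import cis_window
from .preprocess import transform_expression


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``cis_weights`` are the effective per-variant coefficients on the
    standardized-dosage scale; ``trans_edges`` lists
    (index gene, target gene, variance share in the target).
    """

    cis_weights: dict[str, dict[str, float]]
    confounder_loadings: dict[str, list[float]]
    cellcount_loadings: dict[str, list[float]]
    trans_edges: list[tuple[str, str, float]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cis_weights": self.cis_weights,
                    "confounder_loadings": self.confounder_loadings,
                    "cellcount_loadings": self.cellcount_loadings,
                    "trans_edges": [list(e) for e in self.trans_edges],
                    "seed": self.seed,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cis_weights=d["cis_weights"],
            confounder_loadings=d["confounder_loadings"],
            cellcount_loadings=d["cellcount_loadings"],
            trans_edges=[tuple(e) for e in d["trans_edges"]],
            seed=d["seed"],
        )


def generate_genotypes(
    n_samples: int,
    n_variants: int,
    block_size: int = 25,
    rho: float = 0.8,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    variants: list[VariantRecord] | None = None,
    block_sizes: list[int] | None = None,
) -> GenotypeData:
    """LD-blocked biallelic dosages.

    Per haplotype, a latent AR(1) Gaussian (correlation ``rho`` between
    adjacent variants within a block, blocks independent) is thresholded
    at the quantile matching each variant's target MAF; the dosage is the
    sum of the two haplotype alleles.
    """
    if not 0.0 <= rho < 1.0:
        raise DataError(f"rho must be in [0, 1), got {rho}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise DataError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    if variants is None:
        variants = [
            VariantRecord(
                id=f"v{i + 1:06d}", chrom="1", pos=1 + 1000 * i, ref="A", alt="G"
            )
            for i in range(n_variants)
        ]
    if len(variants) != n_variants:
        raise DataError("variants list length != n_variants")
    if block_sizes is None:
        block_sizes = [block_size] * (n_variants // block_size)
        rem = n_variants - sum(block_sizes)
        if rem:
            block_sizes.append(rem)
    if sum(block_sizes) != n_variants:
        raise DataError("block sizes do not sum to n_variants")
    mafs = rng.uniform(lo, hi, n_variants)
    thr = stats.norm.ppf(mafs)
    dosage = np.zeros((n_samples, n_variants))
    sq = np.sqrt(1.0 - rho * rho)
    from scipy.signal import lfilter

    for _hap in range(2):
        start = 0
        for bs in block_sizes:
            E = rng.standard_normal((n_samples, bs)) * sq
            E[:, 0] /= sq  # first variant keeps unit innovation variance
            Z = lfilter([1.0], [1.0, -rho], E, axis=1)
            dosage[:, start : start + bs] += (Z < thr[start : start + bs]).astype(float)
            start += bs
    samples = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypeData(variants=variants, samples=samples, dosage=dosage)


def generate_gene_map(
    n_genes: int,
    n_chroms: int = 2,
    spacing: int = 200_000,
    seed: int = 0,
    gene_length: int = 10_000,
    flank: int = 100_000,
) -> list[GeneAnnotation]:
    """Genes laid out on ``n_chroms`` chromosomes, ``spacing`` bp apart.

    The layout guarantees (for n_genes > 1) that each gene has a
    same-chromosome neighbour within 1 Mb, and a trans candidate either
    beyond 10 Mb or on another chromosome.
    """
    if n_genes < 1:
        raise DataError("n_genes must be >= 1")
    per = -(-n_genes // n_chroms)  # ceil
    if n_genes > 1:
        if spacing + gene_length > 1_000_000:
            raise DataError("spacing too large: genes would have no < 1 Mb neighbour")
        if per < 2 and n_chroms * per >= n_genes:
            per = 2  # keep >= 2 genes per used chromosome
        span = (per - 1) * spacing + gene_length
        if n_chroms < 2 and span <= 10_000_000:
            raise DataError(
                "layout infeasible: no trans candidate beyond 10 Mb on one chromosome"
            )
    genes = []
    i = 0
    chrom = 1
    while i < n_genes:
        for k in range(per):
            if i >= n_genes:
                break
            start = 100_000 + flank + k * spacing
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{i + 1:04d}",
                    chrom=str(chrom),
                    start=start,
                    end=start + gene_length - 1,
                    strand="+" if i % 2 == 0 else "-",
                )
            )
            i += 1
        chrom += 1
    if n_genes > 1:
        for g in genes:
            if not any(
                h is not g and gene_distance(g, h) < 1_000_000 for h in genes
            ):
                raise DataError(f"gene {g.gene_id} has no < 1 Mb neighbour")
    return genes


def variant_map_for_genes(
    annotations: list[GeneAnnotation], n_variants: int, flank: int = 100_000
) -> tuple[list[VariantRecord], list[int]]:
    """Spread variants evenly across each gene's cis window.

    Returns the variant records (sorted by chrom, pos) plus per-window
    block sizes so LD blocks align with cis windows. Because adjacent
    windows overlap when gene spacing < 2*flank + gene length, the
    boundary variants fall in two genes' windows — the raw material for
    local pleiotropy.
    """
    n_genes = len(annotations)
    if n_genes == 0 or n_variants < n_genes:
        raise DataError("need at least one variant per gene")
    per = n_variants // n_genes
    extra = n_variants - per * n_genes
    variants: list[VariantRecord] = []
    block_sizes: list[int] = []
    i = 0
    for k, g in enumerate(sorted(annotations, key=lambda a: (a.chrom, a.start))):
        m = per + (1 if k < extra else 0)
        chrom, lo, hi = cis_window(g, flank)
        pos = np.unique(np.linspace(lo, hi, m).round().astype(int))
        for p in pos:
            i += 1
            variants.append(
                VariantRecord(
                    id=f"v{i:06d}", chrom=chrom, pos=int(p), ref="A", alt="G"
                )
            )
        block_sizes.append(len(pos))
    return variants, block_sizes


def generate_expression(
    geno: GenotypeData,
    annotations: list[GeneAnnotation],
    cis_per_gene: int = 3,
    cis_r2: tuple[float, float] | float = (0.2, 0.4),
    k_confounders: int = 5,
    confounder_sd: float = 0.25,
    cellcount_sd: float = 0.15,
    trans_edges: int | list[tuple[str, str, float]] = 0,
    trans_share: float = 0.2,
    pleiotropy: bool = True,
    pleiotropy_share: float = 0.7,
    cohorts: tuple[str, ...] = ("CO1", "CO2", "CO3"),
    missing_cellcount_frac: float = 0.1,
    min_dist: int = 10_000_000,
    flank: int = 100_000,
    counts: bool = False,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CovariateSet, SyntheticTruth]:
    """Expression with sparse cis architecture, confounding and trans edges.

    Per gene: a standardized cis-genetic score scaled to the target cis R²,
    latent-confounder and cell-count contributions, independent noise; the
    total variance is ~1. With ``pleiotropy``, consecutive same-chromosome
    gene pairs share one cis variant carrying ``pleiotropy_share`` of both
    genes' cis variance, correlating their genetic instruments.
    ``trans_edges`` may be an explicit list of (index, target, variance
    share) or an integer count to auto-place; injected edges always
    respect the > ``min_dist`` trans rule. Returns the transformed
    (within-cohort inverse-normal) expression unless ``counts``, in which
    case negative-binomial counts are returned (scale ``counts``).
    """
    rng = np.random.default_rng(seed)
    ann = sorted(annotations, key=lambda a: (a.chrom, a.start))
    n = geno.n_samples
    n_genes = len(ann)
    vidx = geno.variant_index()
    Z = geno.dosage.copy()
    mu = np.nanmean(Z, axis=0)
    sd = np.nanstd(Z, axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    Z[~np.isfinite(Z)] = 0.0

    window_variants = {
        g.gene_id: [
            v.id
            for v in geno.variants
            if v.chrom == g.chrom
            and cis_window(g, flank)[1] <= v.pos <= cis_window(g, flank)[2]
        ]
        for g in ann
    }

    # pleiotropic pairs: consecutive same-chromosome genes with a variant in
    # the intersection of their cis windows
    shared_variant: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    if pleiotropy:
        used: set[str] = set()
        for a, b in zip(ann, ann[1:]):
            if a.chrom != b.chrom or a.gene_id in used or b.gene_id in used:
                continue
            common = [
                v for v in window_variants[a.gene_id] if v in set(window_variants[b.gene_id])
            ]
            if not common:
                continue
            v_shared = common[len(common) // 2]
            shared_variant[a.gene_id] = v_shared
            shared_variant[b.gene_id] = v_shared
            pairs.append((a.gene_id, b.gene_id))
            used.update((a.gene_id, b.gene_id))

    def _std(x):
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    lo_r2, hi_r2 = (cis_r2, cis_r2) if np.isscalar(cis_r2) else cis_r2
    cis_weights: dict[str, dict[str, float]] = {}
    genetic = np.zeros((n_genes, n))
    r2_used = np.empty(n_genes)
    for gi_, g in enumerate(ann):
        avail = window_variants[g.gene_id]
        if not avail:
            raise DataError(f"gene {g.gene_id} has no cis variant")
        r2 = float(rng.uniform(lo_r2, hi_r2))
        r2_used[gi_] = r2
        v_sh = shared_variant.get(g.gene_id)
        pool = [v for v in avail if v != v_sh]
        k_pick = min(cis_per_gene - (1 if v_sh else 0), len(pool))
        picked = list(rng.choice(pool, size=k_pick, replace=False)) if k_pick else []
        w_raw = rng.normal(size=len(picked))
        rest = (
            _std(Z[:, [vidx[v] for v in picked]] @ w_raw)
            if picked
            else np.zeros(n)
        )
        if v_sh is not None:
            share = pleiotropy_share if picked else 1.0
            score = np.sqrt(share) * Z[:, vidx[v_sh]] / max(
                Z[:, vidx[v_sh]].std(), 1e-12
            ) + np.sqrt(1 - share) * rest
        else:
            score = rest
        score = _std(score)
        genetic[gi_] = np.sqrt(r2) * score
        # effective standardized-scale weights via projection
        cols = picked + ([v_sh] if v_sh else [])
        if cols:
            Xc = Z[:, [vidx[v] for v in cols]]
            beta, *_ = np.linalg.lstsq(Xc, genetic[gi_], rcond=None)
            cis_weights[g.gene_id] = {
                v: float(b) for v, b in zip(cols, beta) if abs(b) > 1e-12
            }
        else:
            cis_weights[g.gene_id] = {}

    F = rng.standard_normal((n, k_confounders)) if k_confounders else np.zeros((n, 0))
    L = (
        rng.normal(0.0, confounder_sd, size=(n_genes, k_confounders))
        if k_confounders
        else np.zeros((n_genes, 0))
    )
    cc = rng.standard_normal((n, 2))
    ccl = rng.normal(0.0, cellcount_sd, size=(n_genes, 2))

    expr = np.empty((n_genes, n))
    for gi_ in range(n_genes):
        struct_var = r2_used[gi_] + np.sum(L[gi_] ** 2) + np.sum(ccl[gi_] ** 2)
        noise_sd = np.sqrt(max(0.05, 1.0 - struct_var))
        expr[gi_] = (
            genetic[gi_]
            + F @ L[gi_]
            + cc @ ccl[gi_]
            + noise_sd * rng.standard_normal(n)
        )

    # trans edges
    gene_ids = [g.gene_id for g in ann]
    gpos = {g.gene_id: g for g in ann}
    gidx = {g: i for i, g in enumerate(gene_ids)}
    if isinstance(trans_edges, int):
        n_edges = trans_edges
        edges: list[tuple[str, str, float]] = []
        if n_edges:
            if not pairs:
                raise DataError(
                    "cannot place trans edges: no neighbouring gene pairs available"
                )
            used_t: set[str] = set()
            for e in range(n_edges):
                idx_gene = pairs[e % len(pairs)][0]
                cands = [
                    t
                    for t in gene_ids
                    if t not in used_t
                    and t != idx_gene
                    and t not in {p for pr in pairs[: n_edges] for p in pr}
                    and gene_distance(gpos[idx_gene], gpos[t]) > min_dist
                ]
                if not cands:
                    raise DataError("no eligible trans target remains")
                tgt = cands[int(rng.integers(len(cands)))]
                used_t.add(tgt)
                edges.append((idx_gene, tgt, trans_share))
    else:
        edges = [(i_, t_, float(s_)) for i_, t_, s_ in trans_edges]
        for i_, t_, _ in edges:
            if i_ not in gidx or t_ not in gidx:
                raise DataError(f"unknown gene in trans edge ({i_}, {t_})")
            if gene_distance(gpos[i_], gpos[t_]) <= min_dist:
                raise DataError(
                    f"trans edge ({i_}, {t_}) violates the > {min_dist} bp rule"
                )
    for i_, t_, s_ in edges:
        expr[gidx[t_]] = np.sqrt(1 - s_) * _std(expr[gidx[t_]]) + np.sqrt(
            s_
        ) * _std(expr[gidx[i_]])

    cohort = np.array([cohorts[i % len(cohorts)] for i in range(n)], dtype=object)
    sex = np.array(["F" if i % 2 == 0 else "M" for i in range(n)], dtype=object)
    age = rng.normal(56.0, 14.8, n)
    rbc = 4.9 + 0.35 * cc[:, 0]
    wbc = 6.8 + 1.6 * cc[:, 1]
    for v in (rbc, wbc):
        if missing_cellcount_frac > 0:
            v[rng.random(n) < missing_cellcount_frac] = np.nan
    cov = CovariateSet(
        samples=list(geno.samples), cohort=cohort, sex=sex, age=age, rbc=rbc, wbc=wbc
    )
    truth = SyntheticTruth(
        cis_weights=cis_weights,
        confounder_loadings={g: L[i].tolist() for i, g in enumerate(gene_ids)},
        cellcount_loadings={g: ccl[i].tolist() for i, g in enumerate(gene_ids)},
        trans_edges=edges,
        seed=seed,
    )
    if counts:
        base_mean = np.exp(rng.uniform(np.log(2.0), np.log(500.0), n_genes))
        mean = base_mean[:, None] * np.exp(0.4 * expr)
        r_disp = 10.0
        vals = rng.negative_binomial(r_disp, r_disp / (r_disp + mean)).astype(float)
        em = ExpressionMatrix(
            genes=gene_ids, samples=list(geno.samples), values=vals, scale="counts"
        )
    else:
        em = transform_expression(
            ExpressionMatrix(
                genes=gene_ids,
                samples=list(geno.samples),
                values=expr,
                scale="logcpm",
            ),
            cohort,
        )
    return em, cov, truth


PRESETS = {
    "tiny": dict(n_samples=200, n_variants=500, n_genes=30, n_chroms=2,
                 trans_edges=2, counts=True),
    "desk": dict(n_samples=2000, n_variants=5000, n_genes=200, n_chroms=4,
                 trans_edges=5, counts=False),
}


def generate_dataset(
    preset: str = "tiny", seed: int = 0, **overrides
) -> tuple[GenotypeData, ExpressionMatrix, CovariateSet, list[GeneAnnotation], SyntheticTruth]:
    """One call from preset name to a coherent in-memory dataset."""
    if preset not in PRESETS:
        raise DataError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = dict(PRESETS[preset])
    p.update(overrides)
    n_samples = p.pop("n_samples")
    n_variants = p.pop("n_variants")
    n_genes = p.pop("n_genes")
    n_chroms = p.pop("n_chroms")
    rho = p.pop("rho", 0.5)
    maf_range = p.pop("maf_range", (0.05, 0.5))
    ann = generate_gene_map(n_genes, n_chroms=n_chroms, seed=seed)
    variants, block_sizes = variant_map_for_genes(ann, n_variants)
    geno = generate_genotypes(
        n_samples,
        len(variants),
        rho=rho,
        maf_range=maf_range,
        seed=seed,
        variants=variants,
        block_sizes=block_sizes,
    )
    expr, cov, truth = generate_expression(
        geno, ann, seed=seed + 1, cis_r2=p.pop("cis_r2", (0.35, 0.45)), **p
    )
    return geno, expr, cov, ann, truth


def write_fixture_bundle(
    directory, preset: str = "tiny", seed: int = 0, force: bool = False
) -> dict[str, str]:
    """Write a complete fixture bundle (VCF + TSVs + truth JSON).

    Refuses to write into an existing non-empty directory unless
    ``force``. Returns the mapping of logical names to file paths.
    """
    directory = str(directory)
    if os.path.isdir(directory) and os.listdir(directory) and not force:
        raise DataError(f"directory {directory} is not empty (use force=True)")
    os.makedirs(directory, exist_ok=True)
    geno, expr, cov, ann, truth = generate_dataset(preset, seed=seed)
    paths = {
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "expression": os.path.join(directory, "expression.tsv"),
        "covariates": os.path.join(directory, "covariates.tsv"),
        "annotation": os.path.join(directory, "annotation.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_dosage_vcf(geno, paths["vcf"])
    write_expression_table(expr, paths["expression"])
    write_covariate_table(cov, paths["covariates"])
    write_annotation_table(ann, paths["annotation"])
    truth.to_json(paths["truth"])
    return paths
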