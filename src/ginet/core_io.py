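"""Domain containers and file I/O for the instrument-network pipeline.

The pipeline works on four kinds of primary data: genotype dosages
(samples x biallelic variants), an RNA-seq expression matrix
(genes x samples), a gene annotation table, and a covariate table
(cohort, sex, age, blood cell counts, optional latent factors).
All coordinates are 1-based inclusive (GTF convention); BED input is
converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "index_gene",
    "target_gene",
    "estimate",
    "se",
    "z_raw",
    "p_raw",
    "z_adj",
    "p_adj",
    "significant",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class EmptyDataError(DataError):
    """An input yielded no usable records."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with 1-based position."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"variant {self.id}: ref == alt ({self.ref})")


@dataclass
class GenotypeData:
    """ALT-allele dosages for samples x variants.

    ``dosage`` is an (n_samples, n_variants) float array with entries in
    [0, 2]; missing entries are NaN.
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate variant IDs")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosage entries must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self) -> dict[str, int]:
        return {v.id: i for i, v in enumerate(self.variants)}

    def subset_variants(self, keep: np.ndarray | list) -> "GenotypeData":
        """Subset by boolean mask or list of variant IDs (order preserved)."""
        if isinstance(keep, (list, tuple)) and keep and isinstance(keep[0], str):
            idx = self.variant_index()
            cols = [idx[v] for v in keep]
        else:
            cols = np.flatnonzero(np.asarray(keep))
        return GenotypeData(
            variants=[self.variants[c] for c in cols],
            samples=list(self.samples),
            dosage=self.dosage[:, cols],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeData":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeData(
            variants=list(self.variants),
            samples=list(sample_ids),
            dosage=self.dosage[rows, :],
        )

    def in_region(self, chrom: str, start: int, end: int) -> "GenotypeData":
        mask = np.array(
            [v.chrom == chrom and start <= v.pos <= end for v in self.variants]
        )
        return self.subset_variants(mask)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates, 1-based inclusive boundaries."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")


def gene_distance(a: GeneAnnotation, b: GeneAnnotation) -> float:
    """Distance between closest gene-body boundaries; 0 if overlapping,
    inf across chromosomes."""
    if a.chrom != b.chrom:
        return float("inf")
    if a.start <= b.end and b.start <= a.end:
        return 0.0
    return float(max(a.start - b.end, b.start - a.end))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a declared scale."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    scale: str = "counts"  # counts | logcpm | int-transformed

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene IDs in expression matrix")
        if self.scale == "counts" and np.nanmin(self.values, initial=0) < 0:
            raise DataError("counts-scale expression must be non-negative")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index()[gene_id], :]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        cols = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(sample_ids),
            values=self.values[:, cols],
            scale=self.scale,
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(
            genes=list(gene_ids),
            samples=list(self.samples),
            values=self.values[rows, :],
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class CovariateSet:
    """Known covariates plus optional latent factors, aligned to samples.

    ``rbc``/``wbc`` may contain NaN (missing measurements);
    ``rbc_observed``/``wbc_observed`` flag which entries were measured
    (as opposed to imputed downstream).
    """

    samples: list[str]
    cohort: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    rbc: np.ndarray | None = None
    wbc: np.ndarray | None = None
    latent: np.ndarray | None = None
    rbc_observed: np.ndarray | None = None
    wbc_observed: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.samples)
        self.cohort = np.asarray(self.cohort, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        for name in ("cohort", "sex", "age"):
            if len(getattr(self, name)) != n:
                raise DataError(f"covariate {name} length != {n} samples")
        for name in ("rbc", "wbc"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise DataError(f"covariate {name} length != {n} samples")
                setattr(self, name, v)
                obs = getattr(self, f"{name}_observed")
                if obs is None:
                    setattr(self, f"{name}_observed", np.isfinite(v))
                else:
                    setattr(self, f"{name}_observed", np.asarray(obs, dtype=bool))
        if self.latent is not None:
            self.latent = np.asarray(self.latent, dtype=float)
            if self.latent.ndim == 1:
                self.latent = self.latent[:, None]
            if self.latent.shape[0] != n:
                raise DataError("latent factor rows != samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def design(
        self,
        include_cellcounts: bool = True,
        include_latent: bool = True,
        fill_missing: bool = True,
    ) -> tuple[np.ndarray, list[str]]:
        """Scaled covariate design matrix (no intercept column).

        Categorical covariates are dummy-coded dropping the first level;
        continuous covariates are standardized. Missing cell counts are
        mean-filled when ``fill_missing`` (callers that cannot tolerate
        imputation-by-mean should run :func:`ginet.preprocess.impute_cell_counts`
        first).
        """
        cols: list[np.ndarray] = []
        names: list[str] = []
        for name, vec in (("cohort", self.cohort), ("sex", self.sex)):
            levels = sorted(set(vec.tolist()))
            for lev in levels[1:]:
                cols.append((vec == lev).astype(float))
                names.append(f"{name}={lev}")
        cols.append(_standardize(self.age))
        names.append("age")
        if include_cellcounts:
            for name in ("rbc", "wbc"):
                v = getattr(self, name)
                if v is None:
                    continue
                v = v.copy()
                if np.any(~np.isfinite(v)):
                    if not fill_missing:
                        raise DataError(f"{name} has missing values")
                    v[~np.isfinite(v)] = np.nanmean(v)
                cols.append(_standardize(v))
                names.append(name)
        if include_latent and self.latent is not None:
            for j in range(self.latent.shape[1]):
                cols.append(_standardize(self.latent[:, j]))
                names.append(f"latent_{j + 1}")
        if not cols:
            return np.empty((self.n_samples, 0)), []
        return np.column_stack(cols), names

    def subset(self, sample_ids: list[str]) -> "CovariateSet":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = np.array([pos[s] for s in sample_ids])

        def take(v):
            return None if v is None else np.asarray(v)[rows]

        return CovariateSet(
            samples=list(sample_ids),
            cohort=self.cohort[rows],
            sex=self.sex[rows],
            age=self.age[rows],
            rbc=take(self.rbc),
            wbc=take(self.wbc),
            latent=None if self.latent is None else self.latent[rows, :],
            rbc_observed=take(self.rbc_observed),
            wbc_observed=take(self.wbc_observed),
        )

    def with_latent(self, latent: np.ndarray) -> "CovariateSet":
        return replace(self, latent=np.asarray(latent, dtype=float))


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class NetworkEdge:
    """A directed index-gene -> target-gene association."""

    index_gene: str
    target_gene: str
    effect: float
    p_adjusted_scale: float
    significant: bool

    def __post_init__(self):
        if self.index_gene == self.target_gene:
            raise DataError("network edge endpoints must differ")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def _parse_region(region) -> tuple[str, int, int]:
    if isinstance(region, (tuple, list)) and len(region) == 3:
        return str(region[0]), int(region[1]), int(region[2])
    m = _REGION_RE.match(str(region))
    if not m:
        raise DataError(f"cannot parse region {region!r}; expected chrom:start-end")
    return m.group(1), int(m.group(2)), int(m.group(3))


def read_dosage_vcf(path, region=None) -> GenotypeData:
    """Read biallelic dosages from a VCF.

    Dosages come from the DS FORMAT field when present; otherwise hard GT
    calls are converted to ALT-allele counts. Multi-allelic records are
    skipped with a warning. ``region`` optionally restricts to
    ``chrom:start-end`` (1-based inclusive, applied while streaming).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises OSError variants
        raise OSError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    want = _parse_region(region) if region is not None else None

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        try:
            ds = v.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            gt = np.asarray(v.gt_types)
            dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        variants.append(
            VariantRecord(id=vid, chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0])
        )
        rows.append(dos)
    vcf.close()
    if n_multi:
        log.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not variants:
        raise EmptyDataError(f"no usable biallelic records in {path}")
    return GenotypeData(
        variants=variants, samples=samples, dosage=np.column_stack(rows)
    )


def write_dosage_vcf(geno: GenotypeData, path) -> None:
    """Write a minimal VCFv4.2 with a DS FORMAT field (text, uncompressed)."""
    order = sorted(
        range(geno.n_variants),
        key=lambda i: (geno.variants[i].chrom, geno.variants[i].pos),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i in order:
            v = geno.variants[i]
            vals = [
                "." if not np.isfinite(d) else f"{d:.6g}" for d in geno.dosage[:, i]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tDS\t"
                + "\t".join(vals)
                + "\n"
            )


def read_expression_table(path, scale: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample IDs).

    The scale is recorded as ``counts`` unless stated otherwise;
    ``scale="auto"`` records counts for non-negative tables and
    ``int-transformed`` when negative values are present (a transformed
    matrix written by this package).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated gene IDs in {path}: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise DataError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}"
                )
        raise
    if scale == "auto":
        scale = "counts" if np.nanmin(values, initial=0) >= 0 else "int-transformed"
    return ExpressionMatrix(
        genes=df.index.astype(str).tolist(),
        samples=df.columns.astype(str).tolist(),
        values=values,
        scale=scale,
    )


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_table(path, bed: bool = False) -> list[GeneAnnotation]:
    """Read a gene annotation table, sorted by (chrom, start).

    Default format: TSV with columns gene_id, chrom, start, end, strand and
    1-based inclusive coordinates. With ``bed=True`` the file is BED-like
    (chrom, start, end, name, score, strand; 0-based half-open) and is
    converted to 1-based inclusive.
    """
    if bed:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        genes = [
            GeneAnnotation(
                gene_id=str(r[3]),
                chrom=str(r[0]),
                start=int(r[1]) + 1,
                end=int(r[2]),
                strand=str(r[5]) if len(r) > 5 else "+",
            )
            for r in df.itertuples(index=False)
        ]
    else:
        df = pd.read_csv(path, sep="\t")
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(df.columns):
            raise DataError(f"annotation table must have columns {sorted(need)}")
        genes = [
            GeneAnnotation(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=str(getattr(r, "strand", "+")),
            )
            for r in df.itertuples(index=False)
        ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate gene IDs in annotation")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def write_annotation_table(genes: list[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write trans-scan results as a TSV with fixed column and row order."""
    df = results.copy() if len(results) else pd.DataFrame(columns=RESULT_COLUMNS)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            raise DataError(f"results missing column {col!r}")
    df = df[RESULT_COLUMNS].sort_values(
        ["index_gene", "target_gene"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_covariate_table(path) -> CovariateSet:
    """Read covariates from a TSV with columns sample_id, cohort, sex, age
    and optional rbc, wbc, latent_1..latent_k."""
    df = pd.read_csv(path, sep="\t")
    latent_cols = sorted(
        (c for c in df.columns if c.startswith("latent_")),
        key=lambda c: int(c.split("_")[1]),
    )
    return CovariateSet(
        samples=df["sample_id"].astype(str).tolist(),
        cohort=df["cohort"].to_numpy(),
        sex=df["sex"].to_numpy(),
        age=df["age"].to_numpy(dtype=float),
        rbc=df["rbc"].to_numpy(dtype=float) if "rbc" in df else None,
        wbc=df["wbc"].to_numpy(dtype=float) if "wbc" in df else None,
        latent=df[latent_cols].to_numpy(dtype=float) if latent_cols else None,
    )


def write_covariate_table(cov: CovariateSet, path) -> None:
    data = {
        "sample_id": cov.samples,
        "cohort": cov.cohort,
        "sex": cov.sex,
        "age": cov.age,
    }
    if cov.rbc is not None:
        data["rbc"] = cov.rbc
    if cov.wbc is not None:
        data["wbc"] = cov.wbc
    if cov.latent is not None:
        for j in range(cov.latent.shape[1]):
            data[f"latent_{j + 1}"] = cov.latent[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
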