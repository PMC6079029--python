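"""End-to-end convenience wrapper: QC -> factors -> split -> instruments ->
trans scan -> network.

The individual stages live in their own modules; this wrapper chains them
with the standard thresholds for in-memory use (tests, scripts, the CLI's
``scan`` command). Expression must already be on the transformed scale;
count matrices go through :func:`ginet.preprocess.cpm_and_filter` and
:func:`ginet.preprocess.transform_expression` first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .confounders import estimate_latent_factors
from .core_io import CovariateSet, ExpressionMatrix, GeneAnnotation, GenotypeData, NetworkEdge
from .instruments import (
    GeneticInstrument,
    InstrumentStrength,
    SampleSplit,
    evaluate_instruments,
    fit_all_instruments,
    split_samples,
)
from .preprocess import QCReport, impute_cell_counts, variant_qc
from .trans_network import (
    ScanConfig,
    bonferroni_threshold,
    build_network,
    run_transwide,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    qc_report: QCReport
    covariates: CovariateSet  # imputed + latent-augmented
    split: SampleSplit
    instruments: dict[str, GeneticInstrument]
    strengths: dict[str, InstrumentStrength]
    kept: dict[str, GeneticInstrument]
    results: pd.DataFrame
    threshold: float
    edges: list[NetworkEdge]
    summary: dict


def edge_recovery(
    results: pd.DataFrame,
    threshold: float,
    truth_edges: list[tuple[str, str, float]],
    annotations: list[GeneAnnotation],
    radius: int = 1_000_000,
) -> dict:
    """Score causal-assignment recovery of known trans edges.

    For each true (index, target) edge, the candidate drivers are the true
    index gene and every scanned gene within ``radius`` of it (the set an
    LD/pleiotropy-confounded scan could confuse). An edge counts as
    *assigned* when the smallest adjusted p among those candidates belongs
    to the true index gene, and as *recovered* when that hit is also
    significant at ``threshold``. ``misassigned`` counts edges whose best
    candidate is a neighbour instead.
    """
    from .core_io import gene_distance

    ann = {g.gene_id: g for g in annotations}
    assigned = recovered = misassigned = 0
    for index_gene, target_gene, _ in truth_edges:
        sub = results[results["target_gene"] == target_gene]
        near = sub[
            [
                gene_distance(ann[index_gene], ann[x]) < radius
                for x in sub["index_gene"]
            ]
        ]
        if not len(near):
            continue
        top = near.loc[near["p_adj"].idxmin()]
        if top["index_gene"] == index_gene:
            assigned += 1
            recovered += int(top["p_adj"] < threshold)
        else:
            misassigned += 1
    return {
        "n_edges": len(truth_edges),
        "assigned": assigned,
        "recovered": recovered,
        "misassigned": misassigned,
    }


def analyze(
    geno: GenotypeData,
    expr: ExpressionMatrix,
    cov: CovariateSet,
    annotations: list[GeneAnnotation],
    config: PipelineConfig | None = None,
    include_neighbours: bool = True,
    null_scope: str = "global",
) -> PipelineResult:
    """Run the full directed-network analysis on transformed expression."""
    cfg = config or PipelineConfig()
    if expr.scale != "int-transformed":
        raise ValueError(
            f"expression must be int-transformed, got scale={expr.scale!r}"
        )
    geno_qc, report = variant_qc(
        geno, maf_min=cfg.maf_min, hwe_alpha=cfg.hwe_alpha,
        call_rate_min=cfg.call_rate_min,
    )
    log.info("variant QC: %d/%d pass", report.n_pass, report.n_input_variants)
    need_impute = any(
        getattr(cov, nm) is not None and not np.all(np.isfinite(getattr(cov, nm)))
        for nm in ("rbc", "wbc")
    )
    if need_impute:
        cov = impute_cell_counts(cov, expr)
    factors = estimate_latent_factors(expr, cov, k=cfg.k_factors)
    cov = cov.with_latent(factors.factors)
    split = split_samples(cov, train_frac=cfg.train_frac, seed=cfg.seed)
    instruments = fit_all_instruments(
        annotations, geno_qc, expr, cov, split,
        flank=cfg.cis_flank, cv_folds=cfg.cv_folds, seed=cfg.seed,
    )
    strengths = evaluate_instruments(
        instruments, annotations, geno_qc, expr, cov, split,
        radius=cfg.neighbour_radius, threshold=cfg.f_threshold,
    )
    kept = {g: gi for g, gi in instruments.items() if strengths[g].keep}
    log.info("instruments: %d fitted, %d kept (F > %g)",
             len(instruments), len(kept), cfg.f_threshold)
    scan_cfg = ScanConfig(
        min_dist=cfg.trans_min_dist,
        neighbour_radius=cfg.neighbour_radius,
        alpha=cfg.alpha,
        null_scope=null_scope,
        include_neighbours=include_neighbours,
    )
    results = run_transwide(kept, geno_qc, expr, cov, annotations, scan_cfg)
    n_index = max(len(kept), 1)
    n_target = max(len(expr.genes), 1)
    threshold = bonferroni_threshold(n_index, n_target, cfg.alpha)
    edges, summary = build_network(results, threshold, annotations,
                                   proximity=cfg.neighbour_radius)
    return PipelineResult(
        qc_report=report,
        covariates=cov,
        split=split,
        instruments=instruments,
        strengths=strengths,
        kept=kept,
        results=results,
        threshold=threshold,
        edges=edges,
        summary=summary,
    )
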