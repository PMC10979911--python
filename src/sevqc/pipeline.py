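"""Workflow composition: per-sample persistence QC and time-course analysis.

These functions tie the stages together in memory; the CLI is a thin file
wrapper around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exogeny import (
    LOW_COUNT_THRESHOLD,
    cds_utr_ratio,
    call_persistence,
    cumulative_expression_fold,
    estimate_enrichment,
    viral_summary,
)
from .genome import ReferenceSet
from .normalize import NormalizationError, cpm_track, size_factors, tpm
from .quantify import (
    CountMatrix,
    CoverageTrack,
    FeatureCounts,
    aggregate_to_genes,
    assign_reads,
    bin_coverage,
    build_index,
    count_features,
    viral_genome_placements,
)
from .simulate import PassageSeries


@dataclass
class QCResult:
    feature_counts: dict[str, FeatureCounts]
    gene_counts: CountMatrix
    size_factors: pd.Series
    tpm: pd.DataFrame
    ratios: pd.DataFrame
    viral: pd.DataFrame
    viral_coverage: dict[str, CoverageTrack] = field(default_factory=dict)
    viral_coverage_cpm: dict[str, CoverageTrack] = field(default_factory=dict)
    assignment_stats: pd.DataFrame | None = None


def quantify_sample(reads, index, models):
    assignments = assign_reads(reads, index)
    return count_features(assignments, models), assignments


def run_qc(
    reference: ReferenceSet,
    sample_reads: dict[str, list[tuple[str, str]]],
    k: int = 31,
    bin_size: int = 100,
    low_count_threshold: int = LOW_COUNT_THRESHOLD,
    min_tpm: float = 0.1,
    min_reads: float = 10,
    factor_genes: list[str] | None = None,
) -> QCResult:
    """Quantify each sample and compute ratios, viral summaries and calls.

    ``sample_reads`` maps sample_id to (read_id, sequence) pairs.  Factor
    ratios are computed for the MANE transcript of every gene in
    ``factor_genes`` (default: all host genes with a MANE flag).
    """
    if not sample_reads:
        raise ValueError("no samples provided")
    index = build_index(reference, k=k)
    models = reference.annotation
    by_id = reference.models_by_id()

    feature_counts: dict[str, FeatureCounts] = {}
    coverage: dict[str, CoverageTrack] = {}
    stats_rows = []
    for sample_id, reads in sample_reads.items():
        fc, assignments = quantify_sample(reads, index, models)
        feature_counts[sample_id] = fc
        tallies = pd.Series([a.status for a in assignments]).value_counts()
        stats_rows.append(
            {
                "sample_id": sample_id,
                "n_reads": len(reads),
                "unique": int(tallies.get("unique", 0)),
                "ambiguous": int(tallies.get("ambiguous", 0)),
                "unassigned": int(tallies.get("unassigned", 0)),
            }
        )
        if reference.viral_model is not None:
            placements = viral_genome_placements(assignments, reference)
            coverage[sample_id] = bin_coverage(
                placements,
                reference.viral_model.length,
                seq_id=reference.viral_model.seq_id,
                bin_size=bin_size,
            )

    transcript_counts = pd.DataFrame(
        {sid: fc.table["total_count"] for sid, fc in feature_counts.items()}
    ).fillna(0.0)
    gene_counts = aggregate_to_genes(transcript_counts, models)
    try:
        factors = size_factors(gene_counts)
    except NormalizationError as exc:
        warnings.warn(f"{exc}; falling back to size factors of 1")
        factors = pd.Series(1.0, index=transcript_counts.columns, name="size_factor")
    expr = tpm(gene_counts)

    if factor_genes is None:
        factor_genes = sorted(
            {
                m.gene_name
                for m in models
                if m.is_mane_select and reference.transcript_origin(m) == "host"
            }
        )
    mane = {
        g: next(m for m in models if m.gene_name == g and m.is_mane_select)
        for g in factor_genes
    }
    ratio_rows = []
    for sample_id, fc in feature_counts.items():
        for gene, model in mane.items():
            rec = cds_utr_ratio(
                fc[model.transcript_id],
                s_j=float(factors[sample_id]),
                gene_name=gene,
                sample_id=sample_id,
                low_count_threshold=low_count_threshold,
            )
            ratio_rows.append(vars(rec))
    ratios = pd.DataFrame(ratio_rows)

    viral_rows = []
    coverage_cpm: dict[str, CoverageTrack] = {}
    if reference.viral_model is not None:
        viral_raw = gene_counts.counts.reindex(
            [g for g in reference.viral_model.genes], fill_value=0.0
        )
        mean_total = float(
            np.mean([len(reads) for reads in sample_reads.values()])
        )
        for sample_id in sample_reads:
            summary = viral_summary(
                expr[sample_id],
                reference.viral_model,
                sample_id=sample_id,
                raw_counts=viral_raw[sample_id],
            )
            call = call_persistence(summary, min_tpm=min_tpm, min_reads=min_reads)
            viral_rows.append(
                {
                    "sample_id": sample_id,
                    "mean_viral_tpm": summary.mean_tpm,
                    "total_viral_reads": summary.total_raw_reads,
                    "excluded_genes": ",".join(sorted(summary.excluded_genes)),
                    "persistence": call,
                }
            )
            coverage_cpm[sample_id] = cpm_track(
                coverage[sample_id], float(factors[sample_id]), mean_total
            )
    viral = pd.DataFrame(viral_rows)

    return QCResult(
        feature_counts=feature_counts,
        gene_counts=gene_counts,
        size_factors=factors,
        tpm=expr,
        ratios=ratios,
        viral=viral,
        viral_coverage=coverage,
        viral_coverage_cpm=coverage_cpm,
        assignment_stats=pd.DataFrame(stats_rows),
    )


def run_timecourse(
    sample_table: pd.DataFrame,
    expression_scale: float | None = None,
) -> pd.DataFrame:
    """Per-condition enrichment fits from a sample-level expression table.

    ``sample_table`` needs columns condition, passage, viral_expression;
    replicates at the same passage are averaged.  Conditions with fewer
    than two passages are skipped with a warning; an empty table is an
    error.
    """
    required = {"condition", "passage", "viral_expression"}
    if sample_table is None or sample_table.empty:
        raise ValueError("empty sample table")
    missing = required - set(sample_table.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    rows = []
    for condition, group in sample_table.groupby("condition", sort=True):
        per_passage = (
            group.groupby("passage")["viral_expression"].mean().sort_index()
        )
        if len(per_passage) < 2:
            warnings.warn(f"condition {condition!r} has <2 passages; skipped")
            continue
        series = PassageSeries(
            passages=[int(p) for p in per_passage.index],
            viral_expression=[float(v) for v in per_passage.values],
            positive_fraction=[float("nan")] * len(per_passage),
        )
        fit = estimate_enrichment(series, expression_scale=expression_scale)
        rows.append(
            {
                "condition": condition,
                "rate_per_passage": fit.rate_per_passage,
                "log2_slope": fit.log2_slope,
                "n_points": fit.n_points,
                "residual_sd": fit.residual_sd,
                "cumulative_fold": cumulative_expression_fold(series),
            }
        )
    if not rows:
        raise ValueError("no condition had at least two passages")
    return pd.DataFrame(rows)
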