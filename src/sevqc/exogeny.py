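"""Exogeny statistics: CDS/UTR ratios, viral summaries, enrichment rates.

The discriminating observation: endogenous mRNAs are transcribed as
CDS+UTR units, while vector-derived transcripts carry only the CDS.  The
ratio of length- and depth-normalized read density on the CDS to that on
the pooled UTRs is therefore ~1 for purely endogenous expression and grows
linearly with the exogenous transcript load (ratio = 1 + e/n for an
exogenous/endogenous copy ratio e/n under uniform fragment sampling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ViralGenomeModel
from .simulate import PassageSeries

#: Raw-count threshold below which a ratio is flagged as low-expression.
LOW_COUNT_THRESHOLD = 30


@dataclass
class RatioRecord:
    """CDS/UTR ratio for one factor transcript in one sample."""

    gene_name: str
    sample_id: str
    ratio: float  # may be +inf when UTR counts are zero
    cds_density: float
    utr_density: float
    total_raw_counts: int
    low_expression: bool
    utr_zero: bool


def cds_utr_ratio(
    fc_row: pd.Series,
    s_j: float = 1.0,
    gene_name: str = "",
    sample_id: str = "",
    low_count_threshold: int = LOW_COUNT_THRESHOLD,
) -> RatioRecord:
    """Length- and depth-normalized CDS over pooled-UTR read density.

    ``fc_row`` is one transcript's row of a FeatureCounts table.  Counts
    are divided by the sample size factor and by the feature length; the
    5' and 3' UTRs are pooled into a single UTR feature before division.
    Zero UTR counts yield +inf with an explicit flag — no pseudocount is
    applied.  Transcripts without UTRs (vector-style models) have no
    defined ratio.
    """
    if s_j <= 0:
        raise ValueError("size factor must be positive")
    cds_len = float(fc_row["cds_length"])
    utr_len = float(fc_row["utr5_length"]) + float(fc_row["utr3_length"])
    if cds_len <= 0:
        raise ValueError("CDS length must be positive")
    if utr_len == 0:
        raise ValueError("ratio undefined for UTR-less transcript")
    cds_count = float(fc_row["cds_count"])
    utr_count = float(fc_row["utr5_count"]) + float(fc_row["utr3_count"])
    cds_density = (cds_count / s_j) / cds_len
    utr_density = (utr_count / s_j) / utr_len
    utr_zero = utr_count == 0 and cds_count > 0
    if utr_count == 0:
        ratio = math.inf if cds_count > 0 else 0.0
    else:
        ratio = cds_density / utr_density
    total_raw = int(round(cds_count + utr_count))
    return RatioRecord(
        gene_name=gene_name,
        sample_id=sample_id,
        ratio=ratio,
        cds_density=cds_density,
        utr_density=utr_density,
        total_raw_counts=total_raw,
        low_expression=total_raw < low_count_threshold,
        utr_zero=utr_zero,
    )


def expected_mixture_ratio(e_over_n: float) -> float:
    """Analytic CDS/UTR ratio for an exogenous/endogenous copy ratio e/n.

    Per-base CDS coverage is proportional to n + e while UTR coverage is
    proportional to n alone, so the expected ratio is 1 + e/n.
    """
    if e_over_n < 0:
        raise ValueError("e/n must be non-negative")
    return 1.0 + e_over_n


def ratio_standard_error(ratio: float, cds_count: float, utr_count: float) -> float:
    """Delta-method Monte-Carlo standard error of a finite, positive ratio.

    Treats the CDS and UTR raw count totals as independent Poisson draws:
    SE(ratio) = ratio * sqrt(1/cds_count + 1/utr_count).
    """
    if cds_count <= 0 or utr_count <= 0:
        raise ValueError("standard error requires positive counts")
    return ratio * math.sqrt(1.0 / cds_count + 1.0 / utr_count)


@dataclass
class ViralSummary:
    """Mean viral gene expression for one sample, minus deleted genes."""

    sample_id: str
    mean_tpm: float
    per_gene_tpm: dict[str, float]
    excluded_genes: set[str]
    total_raw_reads: float = 0.0


def viral_summary(
    expr: pd.Series,
    viral_model: ViralGenomeModel,
    sample_id: str = "",
    excluded: set[str] | None = None,
    raw_counts: pd.Series | None = None,
) -> ViralSummary:
    """Mean TPM over the viral genes carried by the vector.

    ``expr`` is a per-feature TPM column for one sample.  Genes in the
    excluded set (defaulting to the vector's deleted genes, i.e. F) do not
    enter the mean.
    """
    if excluded is None:
        excluded = set(viral_model.deleted_genes)
    present = [g for g in viral_model.genes if g in expr.index]
    if not present:
        raise KeyError("no viral genes present in the expression table")
    per_gene = {g: float(expr[g]) for g in present}
    included = [g for g in present if g not in excluded]
    if not included:
        raise KeyError("all viral genes are excluded from the summary")
    mean_tpm = float(np.mean([per_gene[g] for g in included]))
    total_raw = 0.0
    if raw_counts is not None:
        total_raw = float(sum(raw_counts.get(g, 0.0) for g in included))
    return ViralSummary(
        sample_id=sample_id,
        mean_tpm=mean_tpm,
        per_gene_tpm=per_gene,
        excluded_genes=set(excluded),
        total_raw_reads=total_raw,
    )


def call_persistence(
    summary: ViralSummary,
    min_tpm: float = 0.1,
    min_reads: float = 10,
) -> str:
    """Binary vector-persistence call from a viral expression summary."""
    if min_tpm < 0 or min_reads < 0:
        raise ValueError("thresholds must be non-negative")
    positive = summary.mean_tpm >= min_tpm and summary.total_raw_reads >= min_reads
    return "positive" if positive else "negative"


# ---------------------------------------------------------------------------
# passage-wise enrichment

@dataclass
class EnrichmentFit:
    """Per-passage fold change of viral expression from a log-linear fit."""

    rate_per_passage: float
    log2_slope: float
    intercept: float
    n_points: int
    residual_sd: float


def estimate_enrichment(
    series: PassageSeries,
    expression_scale: float | None = None,
) -> EnrichmentFit:
    """Least-squares log2 fit of viral expression against passage number.

    Zero-expression points are excluded with a warning.  When
    ``expression_scale`` (the expression level at which every cell is
    vector-positive, i.e. per-cell viral expression x 1e6) is given, the
    fit is performed on the log2 odds of the implied positive fraction
    instead of raw expression; this removes the saturation bias that
    flattens the expression curve once positive cells dominate the
    culture.
    """
    pts = [
        (t, e)
        for t, e in zip(series.passages, series.viral_expression)
        if e > 0
    ]
    if len(pts) < len(series.passages):
        warnings.warn(
            f"excluded {len(series.passages) - len(pts)} zero-expression points"
        )
    if expression_scale is not None:
        transformed = []
        for t, e in pts:
            p = e / expression_scale
            if p >= 1:
                warnings.warn(f"passage {t}: implied fraction >= 1; point dropped")
                continue
            transformed.append((t, p / (1 - p)))
        pts = transformed
    if len(pts) < 2:
        raise ValueError("need at least 2 passages with positive expression")
    x = np.array([t for t, _ in pts], dtype=float)
    y = np.log2([v for _, v in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(len(pts) - 2, 1)
    return EnrichmentFit(
        rate_per_passage=float(2.0**slope),
        log2_slope=float(slope),
        intercept=float(intercept),
        n_points=len(pts),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def cumulative_expression_fold(series: PassageSeries) -> float:
    """Viral expression fold between the first and last passage."""
    first = series.viral_expression[0]
    last = series.viral_expression[-1]
    if first <= 0:
        raise ValueError("first passage has zero expression")
    return last / first


def cumulative_cell_enrichment(
    series: PassageSeries,
    expression_scale: float | None = None,
) -> float:
    """Fold enrichment of vector-positive cells, first to last passage.

    Computed as the odds ratio of the positive fraction, the quantity a
    constant per-passage selective advantage compounds into (w^n).  The
    fraction is taken from the series when present, otherwise inferred
    from expression via ``expression_scale``.
    """
    fracs = series.positive_fraction
    if any(math.isnan(p) for p in (fracs[0], fracs[-1])):
        if expression_scale is None:
            raise ValueError(
                "positive fractions unknown; provide expression_scale"
            )
        fracs = [e / expression_scale for e in series.viral_expression]
    p0, p1 = fracs[0], fracs[-1]
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError("fractions must lie strictly inside (0, 1)")
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def per_passage_fold(cumulative_fold: float, n_passages: int) -> float:
    """Geometric per-passage fold implied by a cumulative change.

    A ~1,000-fold difference accrued over 10 passages corresponds to
    1000^(1/10) = 1.995, i.e. approximately two-fold per passage.
    """
    if cumulative_fold <= 0 or n_passages < 1:
        raise ValueError("need positive fold and at least one passage")
    return cumulative_fold ** (1.0 / n_passages)
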