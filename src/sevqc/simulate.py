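"""Synthetic data with the statistical structure the analysis assumes.

Three generators:

* a synthetic reference emulating the four reprogramming-factor transcripts
  (CDS flanked by 5'/3' UTRs, spliced from one or more exons) plus a
  Sendai-like viral genome whose F gene is deleted from the vector;
* a uniform-fragment read simulator producing FASTQ reads from a mixture of
  endogenous (CDS+UTR), exogenous (CDS-only) and viral transcripts, with a
  truth table for parameter-recovery tests;
* a serial-passage selection simulator in which vector-positive cells gain
  a constant per-passage growth advantage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    GenomeInterval,
    ReferenceSet,
    TranscriptModel,
    ViralGenomeModel,
    build_reference,
    cds_sequence,
    derive_utrs,
    transcript_sequence,
    transcript_to_genomic,
)

# ---------------------------------------------------------------------------
# synthetic reference

#: MANE-select transcript per Yamanaka factor (Ensembl/RefSeq agreed ids).
MANE_TRANSCRIPTS = {
    "SOX2": "ENST00000325404",
    "POU5F1": "ENST00000259915",
    "MYC": "ENST00000621592",
    "KLF4": "ENST00000374672",
}

# Feature lengths approximate the real MANE transcripts; exon counts and
# strands follow the genomic loci (SOX2 is single-exon, POU5F1/KLF4 are on
# the minus strand).
FACTOR_GEOMETRY = {
    "SOX2": dict(utr5=423, cds=954, utr3=1141, n_exons=1, strand="+"),
    "POU5F1": dict(utr5=220, cds=1083, utr3=260, n_exons=5, strand="-"),
    "MYC": dict(utr5=520, cds=1365, utr3=495, n_exons=3, strand="+"),
    "KLF4": dict(utr5=180, cds=1443, utr3=1300, n_exons=3, strand="-"),
}

#: Gene intervals of the synthetic Sendai-like genome (0-based half-open).
#: F is carried on the reference genome but deleted from the vector.
VIRAL_GENES = {
    "N": (120, 1845),
    "P": (1900, 3585),
    "M": (3650, 4700),
    "F": (4800, 6500),
    "HN": (6600, 8320),
    "L": (8400, 15130),
}
VIRAL_GENOME_LENGTH = 15384
VIRAL_SEQ_ID = "SeV_genome"
DELETED_VIRAL_GENES = {"F"}

_FLANK = 100
_INTRON = 300


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _factor_model(gene_name: str, contig: str) -> TranscriptModel:
    geom = FACTOR_GEOMETRY[gene_name]
    total = geom["utr5"] + geom["cds"] + geom["utr3"]
    n = geom["n_exons"]
    base, extra = divmod(total, n)
    exon_lens = [base + (1 if i < extra else 0) for i in range(n)]
    exons = []
    pos = _FLANK
    for elen in exon_lens:
        exons.append(GenomeInterval(contig, pos, pos + elen, geom["strand"]))
        pos += elen + _INTRON
    # genomic exon order above is transcript order only on the plus strand
    if geom["strand"] == "-":
        exon_lens.reverse()
    cds = transcript_to_genomic(
        exons, geom["strand"], geom["utr5"], geom["utr5"] + geom["cds"]
    )
    cds = [GenomeInterval(iv.seq_id, iv.start, iv.end, geom["strand"]) for iv in cds]
    utr5, utr3 = derive_utrs(exons, cds, geom["strand"])
    model = TranscriptModel(
        transcript_id=MANE_TRANSCRIPTS[gene_name],
        gene_id=gene_name,
        gene_name=gene_name,
        exons=exons,
        cds=cds,
        utr5=utr5,
        utr3=utr3,
        is_mane_select=True,
    )
    model.validate()
    return model


def synthetic_viral_model() -> ViralGenomeModel:
    return ViralGenomeModel(
        seq_id=VIRAL_SEQ_ID,
        length=VIRAL_GENOME_LENGTH,
        genes={
            name: GenomeInterval(VIRAL_SEQ_ID, s, e)
            for name, (s, e) in VIRAL_GENES.items()
        },
        deleted_genes=set(DELETED_VIRAL_GENES),
    )


def synthetic_reference(seed: int = 0, include_viral: bool = True) -> ReferenceSet:
    """Build the synthetic host+viral reference used throughout the tests."""
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    annotation: list[TranscriptModel] = []
    for gene_name in FACTOR_GEOMETRY:
        contig = f"chr{gene_name}"
        model = _factor_model(gene_name, contig)
        contig_len = max(iv.end for iv in model.exons) + _FLANK
        sequences[contig] = _random_seq(rng, contig_len)
        annotation.append(model)
    viral_sequences = None
    viral_model = None
    if include_viral:
        viral_model = synthetic_viral_model()
        viral_sequences = {VIRAL_SEQ_ID: _random_seq(rng, VIRAL_GENOME_LENGTH)}
    return build_reference(sequences, annotation, viral_sequences, viral_model)


# ---------------------------------------------------------------------------
# expression specifications

@dataclass
class ExpressionSpec:
    """Relative copy levels per transcript source.

    ``endogenous`` and ``exogenous`` are keyed by transcript_id; the
    exogenous entry of a factor contributes CDS-only copies of the same
    transcript (the vector-derived mRNA).  ``viral`` is keyed by viral gene
    name.
    """

    endogenous: dict[str, float] = field(default_factory=dict)
    exogenous: dict[str, float] = field(default_factory=dict)
    viral: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = (
            list(self.endogenous.values())
            + list(self.exogenous.values())
            + list(self.viral.values())
        )
        if any(v < 0 for v in levels):
            raise ValueError("expression levels must be non-negative")
        if not any(v > 0 for v in levels):
            raise ValueError("at least one expression level must be positive")


def endogenous_only_spec(level: float = 1.0) -> ExpressionSpec:
    """All four factors expressed from their endogenous loci only."""
    return ExpressionSpec(
        endogenous={tid: level for tid in MANE_TRANSCRIPTS.values()}
    )


def naive_media_spec(
    myc_e_over_n: float = 99.0,
    sox2_e_over_n: float = 9.0,
    klf4_e_over_n: float = 9.0,
    viral_level: float = 0.5,
) -> ExpressionSpec:
    """Naive-media-like condition: strong exogenous SKM load plus viral genes.

    Defaults place the exogenous/endogenous copy ratio at 99 for MYC and 9
    for SOX2/KLF4, matching the scale of CDS/UTR ratios above 100 and above
    10 seen for these factors under persistent vector expression; OCT4
    (POU5F1) carries no exogenous copies.
    """
    return ExpressionSpec(
        endogenous={tid: 1.0 for tid in MANE_TRANSCRIPTS.values()},
        exogenous={
            MANE_TRANSCRIPTS["MYC"]: myc_e_over_n,
            MANE_TRANSCRIPTS["SOX2"]: sox2_e_over_n,
            MANE_TRANSCRIPTS["KLF4"]: klf4_e_over_n,
        },
        viral={g: viral_level for g in VIRAL_GENES},
    )


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class PoolEntry:
    source_id: str
    sequence: str
    weight: float  # level x length: fragment-level sampling weight
    origin: str  # endogenous | exogenous | viral


@dataclass
class ReadSimConfig:
    """Single-end fixed-length read simulation parameters.

    The 50 bp default matches the short single-end libraries common in the
    bulk RNA-seq studies this analysis targets and keeps reads small
    relative to CDS/UTR feature lengths, which the analytic mixture oracle
    assumes.
    """

    n_reads: int
    read_length: int = 50
    substitution_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.substitution_error_rate <= 1:
            raise ValueError("substitution_error_rate must be in [0, 1]")


def build_transcript_pool(
    reference: ReferenceSet, spec: ExpressionSpec
) -> list[PoolEntry]:
    """Expand an expression spec into concrete (sequence, weight) sources.

    Endogenous entries use the full spliced transcript; exogenous entries
    use the CDS-only sequence of the same transcript; viral entries use the
    gene sequence from the viral genome.  Genes deleted from the vector
    never enter the pool.  Weights are level x length so that per-base
    coverage is proportional to copy level.
    """
    models = reference.models_by_id()
    pool: list[PoolEntry] = []
    for tid, level in spec.endogenous.items():
        if level == 0:
            continue
        if tid not in models:
            raise KeyError(f"unknown transcript id {tid!r}")
        seq = transcript_sequence(models[tid], reference.sequences)
        pool.append(PoolEntry(tid, seq, level * len(seq), "endogenous"))
    for tid, level in spec.exogenous.items():
        if level == 0:
            continue
        if tid not in models:
            raise KeyError(f"unknown transcript id {tid!r}")
        seq = cds_sequence(models[tid], reference.sequences)
        pool.append(PoolEntry(f"{tid}|exogenous", seq, level * len(seq), "exogenous"))
    for gene, level in spec.viral.items():
        if level == 0:
            continue
        vm = reference.viral_model
        if vm is None or gene not in vm.genes:
            raise KeyError(f"unknown viral gene {gene!r}")
        if gene in vm.deleted_genes:
            continue  # absent from the vector: contributes no RNA
        iv = vm.genes[gene]
        seq = reference.sequences[vm.seq_id][iv.start : iv.end]
        pool.append(PoolEntry(gene, seq, level * len(seq), "viral"))
    return pool


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    pool: list[PoolEntry], cfg: ReadSimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw uniform-start fixed-length reads from the pool.

    Returns ``(reads, truth)`` where reads are (read_id, sequence) pairs and
    truth is a DataFrame with columns read_id, source_id, origin.  The same
    seed always yields byte-identical output.  Pool entries shorter than the
    read length are rejected with a warning entry in the truth attrs.
    """
    rng = np.random.default_rng(cfg.seed)
    usable = [e for e in pool if len(e.sequence) >= cfg.read_length]
    skipped = [e.source_id for e in pool if len(e.sequence) < cfg.read_length]
    if not usable:
        raise ValueError("no pool entry is at least read_length long")
    weights = np.array([e.weight for e in usable], dtype=float)
    probs = weights / weights.sum()
    counts = rng.multinomial(cfg.n_reads, probs)

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str, str, int]] = []
    read_no = 0
    for entry, m in zip(usable, counts):
        if m == 0:
            continue
        seq = entry.sequence
        max_start = len(seq) - cfg.read_length
        starts = rng.integers(0, max_start + 1, size=m)
        if cfg.substitution_error_rate > 0:
            n_errors = rng.binomial(cfg.read_length, cfg.substitution_error_rate, size=m)
        else:
            n_errors = np.zeros(m, dtype=int)
        for s, n_err in zip(starts, n_errors):
            read = seq[s : s + cfg.read_length]
            if n_err > 0:
                arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                pos = rng.choice(cfg.read_length, size=n_err, replace=False)
                for p in pos:
                    choices = _BASES[_BASES != arr[p]]
                    arr[p] = rng.choice(choices)
                read = arr.tobytes().decode()
            read_id = f"r{read_no:07d}"
            reads.append((read_id, read))
            truth_rows.append((read_id, entry.source_id, entry.origin, int(s)))
            read_no += 1
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source_id", "origin", "start"]
    )
    truth.attrs["skipped_sources"] = skipped
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], handle) -> None:
    """Write reads as FASTQ with a constant Q40 quality string."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    finally:
        if own:
            fh.close()


def read_fastq(handle) -> list[tuple[str, str]]:
    from Bio import SeqIO

    if isinstance(handle, str) and "\n" in handle:
        handle = io.StringIO(handle)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]


# ---------------------------------------------------------------------------
# serial-passage selection

@dataclass
class PassageSimConfig:
    """Selection dynamics of vector-positive cells across passages.

    Positive cells out-replicate negative ones by a factor ``w`` per
    passage, so the odds p/(1-p) of a cell being vector-positive multiply
    by w each passage.  Bulk viral expression is proportional to the
    positive fraction times the per-cell viral load, sampled as Poisson
    counts at the configured depth.
    """

    p0: float = 1e-3
    w: float = 2.0
    n_passages: int = 10
    per_cell_viral_expression: float = 0.05
    sampling_depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.n_passages < 1:
            raise ValueError("n_passages must be >= 1")


@dataclass
class PassageSeries:
    """Viral expression time course over passages for one condition."""

    passages: list[int]
    viral_expression: list[float]  # mean viral TPM-scale expression
    positive_fraction: list[float]

    def __post_init__(self) -> None:
        if not (
            len(self.passages) == len(self.viral_expression) == len(self.positive_fraction)
        ):
            raise ValueError("series fields must have equal lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "passage": self.passages,
                "viral_expression": self.viral_expression,
                "positive_fraction": self.positive_fraction,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PassageSeries":
        pf = (
            df["positive_fraction"].tolist()
            if "positive_fraction" in df
            else [float("nan")] * len(df)
        )
        return cls(
            passages=[int(p) for p in df["passage"]],
            viral_expression=[float(v) for v in df["viral_expression"]],
            positive_fraction=pf,
        )


def simulate_passages(cfg: PassageSimConfig) -> PassageSeries:
    """Run the odds-multiplication selection model.

    Passage 0 is the initial plating; each subsequent passage multiplies
    the odds of vector positivity by ``w``.  Expected viral expression at
    passage t is ``p_t * per_cell_viral_expression`` of the library, and
    observed expression is Poisson-sampled at ``sampling_depth`` reads.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.p0 == 1.0:
        fractions = [1.0] * (cfg.n_passages + 1)
    else:
        odds0 = cfg.p0 / (1.0 - cfg.p0)
        fractions = [
            (o := odds0 * cfg.w**t) / (1.0 + o) for t in range(cfg.n_passages + 1)
        ]
    lam = np.array(fractions) * cfg.per_cell_viral_expression * cfg.sampling_depth
    counts = rng.poisson(lam)
    expression = counts / cfg.sampling_depth * 1e6
    return PassageSeries(
        passages=list(range(cfg.n_passages + 1)),
        viral_expression=[float(e) for e in expression],
        positive_fraction=[float(p) for p in fractions],
    )
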