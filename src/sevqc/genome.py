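"""Transcript and viral genome models.

Represents host transcripts as exon/CDS/UTR interval structures and the
Sendai-vector genome as a set of UTR-less gene intervals, and builds the
combined host+viral reference the quantifier runs against.

All internal coordinates are 0-based half-open; GTF I/O converts at the
boundary (GTF is 1-based inclusive).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gffutils.feature
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def total_length(intervals: list[GenomeInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def merge_intervals(intervals: list[GenomeInterval]) -> list[GenomeInterval]:
    """Sort and coalesce book-ended or overlapping intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        prev = merged[-1]
        if iv.seq_id == prev.seq_id and iv.start <= prev.end:
            if iv.end > prev.end:
                merged[-1] = replace(prev, end=iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class TranscriptModel:
    """One transcript: exon structure partitioned into CDS and UTRs.

    The invariant maintained throughout is that ``cds + utr5 + utr3``
    exactly tiles the exon bases (pairwise disjoint, no gaps), with utr5
    5' of the CDS in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    exons: list[GenomeInterval]
    cds: list[GenomeInterval] = field(default_factory=list)
    utr5: list[GenomeInterval] = field(default_factory=list)
    utr3: list[GenomeInterval] = field(default_factory=list)
    is_mane_select: bool = False

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def length(self) -> int:
        return total_length(self.exons)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds)

    @property
    def utr5_length(self) -> int:
        return total_length(self.utr5)

    @property
    def utr3_length(self) -> int:
        return total_length(self.utr3)

    def feature_layout(self) -> dict[str, tuple[int, int]]:
        """Feature spans in transcript (spliced, 5'->3') coordinates.

        Returns ``{"utr5": (a, b), "cds": (b, c), "utr3": (c, d)}`` as
        half-open spans; empty features give zero-width spans.
        """
        u5, c = self.utr5_length, self.cds_length
        total = self.length
        return {
            "utr5": (0, u5),
            "cds": (u5, u5 + c),
            "utr3": (u5 + c, total),
        }

    def validate(self) -> None:
        feat_total = self.cds_length + self.utr5_length + self.utr3_length
        if feat_total != self.length:
            raise AnnotationError(
                f"{self.transcript_id}: CDS+UTR bases ({feat_total}) do not "
                f"tile exon bases ({self.length})"
            )
        covered = merge_intervals(self.cds + self.utr5 + self.utr3)
        if covered != merge_intervals(self.exons):
            raise AnnotationError(
                f"{self.transcript_id}: CDS/UTR intervals do not match exons"
            )


@dataclass
class ViralGenomeModel:
    """Gene layout of the viral delivery vector's genome.

    ``deleted_genes`` marks intervals annotated on the reference genome but
    absent from the actual vector (the commercial Sendai kit lacks the
    fusion gene F); they are retained for coverage reporting but excluded
    from expression summaries.
    """

    seq_id: str
    length: int
    genes: dict[str, GenomeInterval]
    deleted_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, iv in self.genes.items():
            if not (0 <= iv.start < iv.end <= self.length):
                raise AnnotationError(
                    f"viral gene {name} interval [{iv.start}, {iv.end}) "
                    f"outside genome [0, {self.length})"
                )

    @property
    def included_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.deleted_genes]


@dataclass
class ReferenceSet:
    """Combined host + viral reference for quantification.

    sequences hold the genomic (contig-level) nucleotide strings; spliced
    transcript sequences are derived on demand via transcript_sequences().
    """

    sequences: dict[str, str]
    origin: dict[str, str]  # seq_id -> "host" | "viral"
    annotation: list[TranscriptModel]
    viral_model: ViralGenomeModel | None = None

    def __post_init__(self) -> None:
        for model in self.annotation:
            for iv in model.exons:
                if iv.seq_id not in self.sequences:
                    raise AnnotationError(
                        f"{model.transcript_id} refers to unknown sequence "
                        f"{iv.seq_id!r}"
                    )

    def models_by_id(self) -> dict[str, TranscriptModel]:
        return {m.transcript_id: m for m in self.annotation}

    def transcript_sequences(self) -> dict[str, str]:
        return {
            m.transcript_id: transcript_sequence(m, self.sequences)
            for m in self.annotation
        }

    def transcript_origin(self, model: TranscriptModel) -> str:
        return self.origin[model.seq_id]


# ---------------------------------------------------------------------------
# sequence extraction

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _splice(intervals: list[GenomeInterval], sequences: dict[str, str]) -> str:
    parts = [sequences[iv.seq_id][iv.start : iv.end] for iv in sorted(
        intervals, key=lambda iv: iv.start)]
    return "".join(parts)


def transcript_sequence(model: TranscriptModel, sequences: dict[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    seq = _splice(model.exons, sequences)
    return reverse_complement(seq) if model.strand == "-" else seq


def cds_sequence(model: TranscriptModel, sequences: dict[str, str]) -> str:
    """Spliced CDS-only sequence in transcript orientation."""
    seq = _splice(model.cds, sequences)
    return reverse_complement(seq) if model.strand == "-" else seq


def transcript_to_genomic(
    exons: list[GenomeInterval], strand: str, t_start: int, t_end: int
) -> list[GenomeInterval]:
    """Map a transcript-coordinate span [t_start, t_end) to genomic intervals.

    Transcript coordinate 0 is the 5' end of the spliced transcript; on the
    minus strand that is the genomic-rightmost exon base.
    """
    if t_start < 0 or t_end <= t_start:
        raise ValueError("need 0 <= t_start < t_end")
    ordered = sorted(exons, key=lambda iv: iv.start, reverse=(strand == "-"))
    out: list[GenomeInterval] = []
    offset = 0
    for exon in ordered:
        elen = len(exon)
        lo = max(t_start - offset, 0)
        hi = min(t_end - offset, elen)
        if lo < hi:
            if strand == "+":
                out.append(replace(exon, start=exon.start + lo, end=exon.start + hi))
            else:
                out.append(replace(exon, start=exon.end - hi, end=exon.end - lo))
        offset += elen
    if total_length(out) != t_end - t_start:
        raise ValueError("span extends beyond transcript length")
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# UTR derivation

def derive_utrs(
    exons: list[GenomeInterval],
    cds: list[GenomeInterval],
    strand: str,
) -> tuple[list[GenomeInterval], list[GenomeInterval]]:
    """Partition non-CDS exon bases into 5' and 3' UTRs.

    Exon bases genomically left of the CDS go to the left flank, bases right
    of it to the right flank; which flank is the 5' UTR depends on strand.
    Requires the CDS to be contiguous in transcript coordinates (all exon
    bases between the outermost CDS bases belong to the CDS).
    """
    if not cds:
        raise AnnotationError("derive_utrs requires a non-empty CDS")
    exons = merge_intervals(exons)
    cds = merge_intervals(cds)
    for c in cds:
        if not any(e.start <= c.start and c.end <= e.end for e in exons):
            raise AnnotationError(
                f"CDS interval [{c.start}, {c.end}) not contained in exons"
            )
    cds_lo = cds[0].start
    cds_hi = cds[-1].end
    left: list[GenomeInterval] = []
    right: list[GenomeInterval] = []
    interior = 0
    for e in exons:
        if e.start < cds_lo:
            left.append(replace(e, end=min(e.end, cds_lo)))
        if e.end > cds_hi:
            right.append(replace(e, start=max(e.start, cds_hi)))
        interior += max(0, min(e.end, cds_hi) - max(e.start, cds_lo))
    if interior != total_length(cds):
        raise AnnotationError(
            "CDS is not contiguous in transcript coordinates "
            "(exon bases interleave with the CDS span)"
        )
    return (left, right) if strand == "+" else (right, left)


# ---------------------------------------------------------------------------
# GTF I/O

_TRANSCRIPT_FEATURES = {"exon", "CDS", "stop_codon"}


def load_annotation(gtf_stream) -> list[TranscriptModel]:
    """Parse exon/CDS features from a GTF text stream into transcript models.

    Stop codons annotated outside the CDS are folded into it so that the
    CDS/UTR tiling stays exact.  UTRs are always re-derived from exon and
    CDS structure.  MANE-select status is read from ``tag "MANE_Select"``.
    """
    if isinstance(gtf_stream, str):
        gtf_stream = io.StringIO(gtf_stream)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: expected 9 tab-separated "
                f"fields, got {len(line.split(chr(9)))}"
            )
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:
            raise AnnotationError(f"GTF parse error at line {lineno}: {exc}") from exc
        if feat.featuretype not in _TRANSCRIPT_FEATURES:
            continue
        attrs = feat.attributes
        try:
            tx_id = attrs["transcript_id"][0]
        except KeyError:
            raise AnnotationError(
                f"GTF line {lineno}: {feat.featuretype} feature without "
                "transcript_id"
            )
        if feat.strand not in ("+", "-"):
            raise AnnotationError(f"GTF line {lineno}: missing strand")
        iv = GenomeInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        rec = per_tx.get(tx_id)
        if rec is None:
            rec = {
                "gene_id": attrs.get("gene_id", [tx_id])[0],
                "gene_name": attrs.get("gene_name", attrs.get("gene_id", [tx_id]))[0],
                "exon": [],
                "CDS": [],
                "stop_codon": [],
                "mane": False,
            }
            per_tx[tx_id] = rec
            order.append(tx_id)
        rec[feat.featuretype].append(iv)
        if "MANE_Select" in attrs.get("tag", []):
            rec["mane"] = True

    models = []
    for tx_id in order:
        rec = per_tx[tx_id]
        if not rec["exon"]:
            raise AnnotationError(f"transcript {tx_id} has no exon features")
        exons = merge_intervals(rec["exon"])
        cds = merge_intervals(rec["CDS"] + rec["stop_codon"])
        if cds:
            utr5, utr3 = derive_utrs(exons, cds, exons[0].strand)
        else:
            cds, utr5, utr3 = exons, [], []
        model = TranscriptModel(
            transcript_id=tx_id,
            gene_id=rec["gene_id"],
            gene_name=rec["gene_name"],
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            is_mane_select=rec["mane"],
        )
        model.validate()
        models.append(model)
    return models


def write_annotation(models: list[TranscriptModel]) -> str:
    """Serialize transcript models back to GTF (exon + CDS lines)."""
    lines = []
    for m in models:
        tags = ' tag "MANE_Select";' if m.is_mane_select else ""
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_name "{m.gene_name}";{tags}'
        )
        for ftype, ivs in (("exon", m.exons), ("CDS", m.cds)):
            # viral-style models with cds == exons emit both line types
            if ftype == "CDS" and m.cds == m.exons and not m.utr5 and not m.utr3:
                ivs = m.exons
            for iv in ivs:
                lines.append(
                    "\t".join(
                        [
                            iv.seq_id,
                            "sevqc",
                            ftype,
                            str(iv.start + 1),
                            str(iv.end),
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


def select_mane(annotation: list[TranscriptModel], gene_name: str) -> TranscriptModel:
    """Return the unique MANE-select transcript of a gene."""
    hits = [
        m for m in annotation if m.gene_name == gene_name and m.is_mane_select
    ]
    if not hits:
        raise AnnotationError(f"no MANE transcript for gene {gene_name!r}")
    if len(hits) > 1:
        ids = ", ".join(m.transcript_id for m in hits)
        raise AnnotationError(
            f"ambiguous MANE annotation for {gene_name!r}: {ids}"
        )
    return hits[0]


# ---------------------------------------------------------------------------
# FASTA + viral gene table I/O and reference assembly

def load_fasta(handle) -> dict[str, str]:
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def load_viral_gene_table(stream, seq_id: str, length: int) -> ViralGenomeModel:
    """Read a viral gene TSV (name, start, end, deleted) into a genome model.

    Coordinates in the table are 0-based half-open.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genes: dict[str, GenomeInterval] = {}
    deleted: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AnnotationError(f"viral gene table line {lineno}: need >=3 columns")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        genes[name] = GenomeInterval(seq_id, start, end)
        if len(parts) > 3 and parts[3].strip().lower() in ("1", "true", "yes", "deleted"):
            deleted.add(name)
    return ViralGenomeModel(seq_id=seq_id, length=length, genes=genes, deleted_genes=deleted)


VIRAL_NAMESPACE = "viral|"


def viral_gene_models(viral_model: ViralGenomeModel) -> list[TranscriptModel]:
    """Viral genes as UTR-less single-exon plus-strand transcript models.

    The vector transcribes bare coding units, so each gene is modeled as a
    transcript whose CDS spans the whole exon; the quantifier then treats
    host and viral features uniformly.
    """
    models = []
    for name, iv in viral_model.genes.items():
        exon = GenomeInterval(viral_model.seq_id, iv.start, iv.end, "+")
        models.append(
            TranscriptModel(
                transcript_id=name,
                gene_id=name,
                gene_name=name,
                exons=[exon],
                cds=[exon],
            )
        )
    return models


def build_reference(
    host_sequences: dict[str, str],
    host_annotation: list[TranscriptModel],
    viral_sequences: dict[str, str] | None = None,
    viral_model: ViralGenomeModel | None = None,
) -> ReferenceSet:
    """Assemble the combined host+viral reference in a single namespace.

    On a seq_id collision between host and viral inputs the viral sequence
    (and its gene models) are renamed with the ``viral|`` prefix.
    """
    sequences = dict(host_sequences)
    origin = {sid: "host" for sid in host_sequences}
    annotation = list(host_annotation)

    if viral_sequences:
        if viral_model is None:
            raise AnnotationError("viral sequences given without a gene model")
        vseq_id = viral_model.seq_id
        if vseq_id not in viral_sequences:
            raise AnnotationError(
                f"viral model seq_id {vseq_id!r} not among viral sequences"
            )
        if vseq_id in sequences:
            new_id = VIRAL_NAMESPACE + vseq_id
            if new_id in sequences:
                raise AnnotationError(f"seq_id collision on {new_id!r}")
            viral_model = ViralGenomeModel(
                seq_id=new_id,
                length=viral_model.length,
                genes={
                    n: replace(iv, seq_id=new_id)
                    for n, iv in viral_model.genes.items()
                },
                deleted_genes=set(viral_model.deleted_genes),
            )
            viral_sequences = {new_id: viral_sequences[vseq_id]}
            vseq_id = new_id
        if len(viral_sequences[vseq_id]) != viral_model.length:
            raise AnnotationError(
                "viral genome length does not match the gene model"
            )
        sequences[vseq_id] = viral_sequences[vseq_id]
        origin[vseq_id] = "viral"
        annotation.extend(viral_gene_models(viral_model))
    else:
        viral_model = None

    return ReferenceSet(
        sequences=sequences,
        origin=origin,
        annotation=annotation,
        viral_model=viral_model,
    )
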