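"""Exact k-mer voting quantifier.

Reads are assigned to reference transcripts by counting shared k-mers:
every k-mer of a read votes for the transcripts containing it (either
strand), the transcripts with the maximal vote win, and ties are split into
equal fractional weights.  Assignments feed three tabulations: per-feature
(CDS/UTR5/UTR3) counts, binned coverage tracks, and gene-level count
matrices.  No indels, no EM — the downstream statistic needs positional
read density, not isoform resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ReferenceSet, TranscriptModel, reverse_complement


@dataclass
class KmerIndex:
    k: int
    table: dict[str, tuple[tuple[str, int], ...]]
    seq_lengths: dict[str, int]

    def query(self, kmer: str) -> tuple[tuple[str, int], ...]:
        return self.table.get(kmer, ())


def build_index(reference: ReferenceSet | dict[str, str], k: int = 31) -> KmerIndex:
    """Index every k-mer of every spliced transcript, both strands.

    The reverse complement of each reference k-mer maps to the same
    (seq_id, forward offset) hits, so querying a k-mer or its reverse
    complement returns the same set.  Sequences shorter than k are skipped
    with a warning.
    """
    import warnings

    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if isinstance(reference, ReferenceSet):
        seqs = reference.transcript_sequences()
    else:
        seqs = reference
    table: dict[str, list[tuple[str, int]]] = {}
    lengths: dict[str, int] = {}
    for seq_id, seq in seqs.items():
        if len(seq) < k:
            warnings.warn(f"sequence {seq_id!r} shorter than k={k}; skipped")
            continue
        lengths[seq_id] = len(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            hit = (seq_id, i)
            table.setdefault(kmer, []).append(hit)
            rc = reverse_complement(kmer)
            if rc != kmer:
                table.setdefault(rc, []).append(hit)
    return KmerIndex(
        k=k,
        table={kmer: tuple(hits) for kmer, hits in table.items()},
        seq_lengths=lengths,
    )


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # unique | ambiguous | unassigned
    targets: dict[str, float] = field(default_factory=dict)
    position: int | None = None  # 5'-most offset on the primary target
    positions: dict[str, int] = field(default_factory=dict)
    read_length: int = 0


def default_min_votes(read_length: int, k: int, max_mismatches: int = 3) -> int:
    """Votes required to call a read assigned.

    Each substitution destroys up to k of the read's ``read_length - k + 1``
    k-mers; the default tolerates up to ``max_mismatches`` substitutions and
    never drops below one exact shared k-mer.
    """
    return max(1, read_length - k + 1 - max_mismatches * k)


def assign_read(
    read: str,
    index: KmerIndex,
    read_id: str = "",
    min_votes: int | None = None,
) -> ReadAssignment:
    """Vote the read's k-mers against the index and pick the winner(s)."""
    k = index.k
    n_kmers = len(read) - k + 1
    if n_kmers < 1:
        return ReadAssignment(read_id, "unassigned", read_length=len(read))
    if min_votes is None:
        min_votes = default_min_votes(len(read), k)
    votes: Counter[str] = Counter()
    hit_list: list[tuple[int, tuple[tuple[str, int], ...]]] = []
    table = index.table
    for i in range(n_kmers):
        hits = table.get(read[i : i + k])
        if hits:
            hit_list.append((i, hits))
            for seq_id, _off in hits:
                votes[seq_id] += 1
    if not votes:
        return ReadAssignment(read_id, "unassigned", read_length=len(read))
    top = max(votes.values())
    if top < min_votes:
        return ReadAssignment(read_id, "unassigned", read_length=len(read))
    winners = sorted(s for s, v in votes.items() if v == top)
    weight = 1.0 / len(winners)
    positions: dict[str, int] = {}
    for target in winners:
        starts = Counter()
        for i, hits in hit_list:
            for seq_id, off in hits:
                if seq_id == target:
                    starts[max(0, off - i)] += 1
        positions[target] = starts.most_common(1)[0][0]
    status = "unique" if len(winners) == 1 else "ambiguous"
    return ReadAssignment(
        read_id=read_id,
        status=status,
        targets={t: weight for t in winners},
        position=positions[winners[0]],
        positions=positions,
        read_length=len(read),
    )


def assign_reads(
    reads: list[tuple[str, str]],
    index: KmerIndex,
    min_votes: int | None = None,
) -> list[ReadAssignment]:
    return [assign_read(seq, index, read_id=rid, min_votes=min_votes) for rid, seq in reads]


# ---------------------------------------------------------------------------
# feature counting

FEATURE_COLUMNS = [
    "cds_count",
    "utr5_count",
    "utr3_count",
    "total_count",
    "cds_length",
    "utr5_length",
    "utr3_length",
]


@dataclass
class FeatureCounts:
    """Per-transcript CDS/UTR5/UTR3 counts with feature lengths (one sample)."""

    table: pd.DataFrame  # index transcript_id, columns FEATURE_COLUMNS

    def __getitem__(self, transcript_id: str) -> pd.Series:
        return self.table.loc[transcript_id]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="transcript_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureCounts":
        return cls(pd.read_csv(path, sep="\t", index_col="transcript_id"))


def count_features(
    assignments: list[ReadAssignment],
    models: list[TranscriptModel],
) -> FeatureCounts:
    """Accumulate assignment weights into CDS/UTR feature counts.

    A read contributes its weight to every feature type it overlaps by at
    least one base (a junction-spanning read counts into both flanking
    features).  Assignments to targets without a transcript model are
    tallied at the transcript level only.
    """
    by_id = {m.transcript_id: m for m in models}
    layouts = {tid: m.feature_layout() for tid, m in by_id.items()}
    rows: dict[str, np.ndarray] = {}

    def _row(tid: str) -> np.ndarray:
        row = rows.get(tid)
        if row is None:
            row = np.zeros(4)
            rows[tid] = row
        return row

    for a in assignments:
        if not a.targets:
            continue
        for tid, weight in a.targets.items():
            row = _row(tid)
            row[3] += weight
            layout = layouts.get(tid)
            if layout is None:
                continue
            pos = a.positions.get(tid, a.position or 0)
            span = (pos, pos + a.read_length)
            for j, feat in enumerate(("cds", "utr5", "utr3")):
                lo, hi = layout[feat]
                if span[0] < hi and lo < span[1]:
                    row[j] += weight

    index = sorted(set(rows) | set(by_id))
    data = []
    for tid in index:
        row = rows.get(tid, np.zeros(4))
        m = by_id.get(tid)
        lengths = (
            (m.cds_length, m.utr5_length, m.utr3_length) if m else (0, 0, 0)
        )
        data.append(list(row) + list(lengths))
    table = pd.DataFrame(data, index=pd.Index(index, name="transcript_id"),
                         columns=FEATURE_COLUMNS)
    return FeatureCounts(table)


# ---------------------------------------------------------------------------
# coverage tracks

@dataclass
class CoverageTrack:
    seq_id: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def total(self) -> float:
        return float(self.values.sum())


def bin_coverage(
    placements: list[tuple[int, float]],
    seq_length: int,
    seq_id: str = "",
    bin_size: int = 100,
) -> CoverageTrack:
    """Bin read placements by 5'-most base into fixed-width bins.

    ``placements`` are (position, weight) pairs.  Values sum exactly to the
    total placed weight, preserving the conservation invariant.
    """
    n_bins = -(-seq_length // bin_size)
    values = np.zeros(n_bins)
    for pos, weight in placements:
        if not 0 <= pos < seq_length:
            raise ValueError(f"position {pos} outside [0, {seq_length})")
        values[pos // bin_size] += weight
    return CoverageTrack(seq_id=seq_id, bin_size=bin_size, values=values)


def viral_genome_placements(
    assignments: list[ReadAssignment],
    reference: ReferenceSet,
) -> list[tuple[int, float]]:
    """Project viral-gene assignments onto viral genome coordinates."""
    vm = reference.viral_model
    if vm is None:
        return []
    placements = []
    for a in assignments:
        for tid, weight in a.targets.items():
            iv = vm.genes.get(tid)
            if iv is not None:
                pos = a.positions.get(tid, a.position or 0)
                placements.append((iv.start + pos, weight))
    return placements


def write_bedgraph(track: CoverageTrack, handle, seq_length: int | None = None) -> None:
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for i, v in enumerate(track.values):
            start = i * track.bin_size
            end = start + track.bin_size
            if seq_length is not None:
                end = min(end, seq_length)
            fh.write(f"{track.seq_id}\t{start}\t{end}\t{v:.6g}\n")
    finally:
        if own:
            fh.close()


def read_bedgraph(handle) -> CoverageTrack:
    import io as _io

    if isinstance(handle, str) and "\n" in handle:
        handle = _io.StringIO(handle)
    elif isinstance(handle, str):
        handle = open(handle)
    seq_id = ""
    values = []
    bin_size = None
    for line in handle:
        parts = line.split("\t")
        seq_id, start, end, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if bin_size is None and end - start > 0:
            bin_size = end - start
        values.append(v)
    return CoverageTrack(seq_id=seq_id, bin_size=bin_size or 100, values=np.array(values))


# ---------------------------------------------------------------------------
# gene aggregation

@dataclass
class CountMatrix:
    """Raw counts, features x samples, with per-feature lengths."""

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths.dropna() <= 0).any():
            raise ValueError("feature lengths must be positive")

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        lengths = df.pop("length")
        return cls(counts=df, lengths=lengths)


def aggregate_to_genes(
    transcript_counts: pd.DataFrame,
    annotation: list[TranscriptModel],
) -> CountMatrix:
    """Sum transcript counts to gene level.

    Gene length is the MANE transcript's spliced length when one is
    flagged, otherwise the longest transcript.  Transcripts without a model
    are kept under their own id with a warning.
    """
    import warnings

    by_id = {m.transcript_id: m for m in annotation}
    gene_of: dict[str, str] = {}
    for tid in transcript_counts.index:
        m = by_id.get(tid)
        if m is None:
            warnings.warn(f"transcript {tid!r} has no model; kept as its own gene")
            gene_of[tid] = tid
        else:
            gene_of[tid] = m.gene_id
    grouped = transcript_counts.groupby(
        transcript_counts.index.map(gene_of.get)
    ).sum()
    grouped.index.name = "feature_id"

    lengths = {}
    for gene in grouped.index:
        members = [m for m in annotation if m.gene_id == gene]
        if not members:
            lengths[gene] = np.nan
            continue
        mane = [m for m in members if m.is_mane_select]
        chosen = mane[0] if len(mane) == 1 else max(members, key=lambda m: m.length)
        lengths[gene] = chosen.length
    return CountMatrix(counts=grouped, lengths=pd.Series(lengths, name="length"))
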