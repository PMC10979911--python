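"""Transcript model construction: coordinates, UTR derivation, GTF I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from sevqc.genome import (
    AnnotationError,
    GenomeInterval,
    TranscriptModel,
    ViralGenomeModel,
    build_reference,
    derive_utrs,
    load_annotation,
    merge_intervals,
    reverse_complement,
    select_mane,
    total_length,
    transcript_sequence,
    transcript_to_genomic,
    write_annotation,
)
from sevqc.simulate import MANE_TRANSCRIPTS

GTF_LINE = (
    "{seq}\tsrc\t{feat}\t{start}\t{end}\t.\t{strand}\t.\t"
    'gene_id "{gene}"; transcript_id "{tx}"; gene_name "{name}";{extra}\n'
)


def make_gtf(features, gene="G1", tx="T1", name="GENE1", seq="chr1", extra=""):
    return "".join(
        GTF_LINE.format(
            seq=seq, feat=f, start=s, end=e, strand=strand, gene=gene, tx=tx,
            name=name, extra=extra,
        )
        for f, s, e, strand in features
    )


class TestDeriveUtrs:
    @pytest.mark.parametrize(
        "strand,utr5_expect,utr3_expect",
        [
            ("+", [(0, 100)], [(200, 300)]),
            ("-", [(200, 300)], [(0, 100)]),
        ],
    )
    def test_single_exon_strand_symmetry(self, strand, utr5_expect, utr3_expect):
        exons = [GenomeInterval("c", 0, 300, strand)]
        cds = [GenomeInterval("c", 100, 200, strand)]
        utr5, utr3 = derive_utrs(exons, cds, strand)
        assert [(iv.start, iv.end) for iv in utr5] == utr5_expect
        assert [(iv.start, iv.end) for iv in utr3] == utr3_expect

    def test_cds_equals_exons_gives_empty_utrs(self):
        exons = [GenomeInterval("c", 0, 300)]
        utr5, utr3 = derive_utrs(exons, exons, "+")
        assert utr5 == [] and utr3 == []

    def test_cds_outside_exons_rejected(self):
        exons = [GenomeInterval("c", 0, 300)]
        cds = [GenomeInterval("c", 250, 350)]
        with pytest.raises(AnnotationError):
            derive_utrs(exons, cds, "+")

    def test_noncontiguous_cds_rejected(self):
        # exon bases between the two CDS pieces are neither CDS nor flank
        exons = [GenomeInterval("c", 0, 300)]
        cds = [GenomeInterval("c", 50, 100), GenomeInterval("c", 200, 250)]
        with pytest.raises(AnnotationError):
            derive_utrs(exons, cds, "+")

    @given(
        exon_lens=st.lists(st.integers(20, 200), min_size=1, max_size=4),
        intron=st.integers(10, 100),
        data=st.data(),
        strand=st.sampled_from("+-"),
    )
    @settings(max_examples=100, deadline=None)
    def test_tiling_invariant(self, exon_lens, intron, data, strand):
        """CDS + UTR5 + UTR3 always tile the exon bases exactly."""
        exons = []
        pos = 0
        for elen in exon_lens:
            exons.append(GenomeInterval("c", pos, pos + elen, strand))
            pos += elen + intron
        total = sum(exon_lens)
        t_start = data.draw(st.integers(0, total - 2))
        t_end = data.draw(st.integers(t_start + 1, total - 1)) + 1
        cds = transcript_to_genomic(exons, strand, t_start, t_end)
        utr5, utr3 = derive_utrs(exons, cds, strand)
        assert (
            total_length(cds) + total_length(utr5) + total_length(utr3) == total
        )
        assert merge_intervals(cds + utr5 + utr3) == merge_intervals(exons)
        # strand involution: flipping strand swaps the UTR assignments
        flipped = "-" if strand == "+" else "+"
        u5f, u3f = derive_utrs(exons, cds, flipped)
        assert (u5f, u3f) == (utr3, utr5)


class TestLoadAnnotation:
    def test_coordinate_conversion(self):
        """GTF exon 100-400 / CDS 150-350 gives UTRs [99,149) and [350,400)."""
        gtf = make_gtf([("exon", 100, 400, "+"), ("CDS", 150, 350, "+")])
        (model,) = load_annotation(gtf)
        assert [(iv.start, iv.end) for iv in model.utr5] == [(99, 149)]
        assert [(iv.start, iv.end) for iv in model.utr3] == [(350, 400)]
        assert [(iv.start, iv.end) for iv in model.cds] == [(149, 350)]

    def test_cds_spanning_whole_exon(self):
        gtf = make_gtf([("exon", 100, 400, "+"), ("CDS", 100, 400, "+")])
        (model,) = load_annotation(gtf)
        assert model.utr5 == [] and model.utr3 == []

    def test_minus_strand_swaps_utrs(self):
        plus = load_annotation(
            make_gtf([("exon", 100, 400, "+"), ("CDS", 150, 350, "+")])
        )[0]
        minus = load_annotation(
            make_gtf([("exon", 100, 400, "-"), ("CDS", 150, 350, "-")])
        )[0]
        assert [(iv.start, iv.end) for iv in minus.utr5] == [
            (iv.start, iv.end) for iv in plus.utr3
        ]

    def test_stop_codon_folded_into_cds(self):
        gtf = make_gtf(
            [("exon", 1, 100, "+"), ("CDS", 10, 60, "+"), ("stop_codon", 61, 63, "+")]
        )
        (model,) = load_annotation(gtf)
        assert [(iv.start, iv.end) for iv in model.cds] == [(9, 63)]
        assert [(iv.start, iv.end) for iv in model.utr3] == [(63, 100)]

    def test_malformed_line_names_line_number(self):
        gtf = make_gtf([("exon", 1, 100, "+")]) + "not a gtf line\n"
        with pytest.raises(AnnotationError, match="line 2"):
            load_annotation(gtf)

    def test_cds_outside_exons_is_validation_error(self):
        gtf = make_gtf([("exon", 100, 200, "+"), ("CDS", 150, 250, "+")])
        with pytest.raises(AnnotationError):
            load_annotation(gtf)

    def test_round_trip(self, reference):
        models = reference.annotation
        reparsed = load_annotation(write_annotation(models))
        assert len(reparsed) == len(models)
        for a, b in zip(models, reparsed):
            assert a.transcript_id == b.transcript_id
            assert a.exons == b.exons
            assert a.cds == b.cds
            assert a.utr5 == b.utr5
            assert a.utr3 == b.utr3
            assert a.is_mane_select == b.is_mane_select


class TestSelectMane:
    def test_known_factor_transcripts(self, reference):
        assert (
            select_mane(reference.annotation, "KLF4").transcript_id
            == "ENST00000374672"
        )
        assert (
            select_mane(reference.annotation, "MYC").transcript_id
            == "ENST00000621592"
        )
        assert MANE_TRANSCRIPTS["SOX2"] == select_mane(
            reference.annotation, "SOX2"
        ).transcript_id

    def test_missing_and_ambiguous(self):
        gtf = make_gtf([("exon", 1, 100, "+"), ("CDS", 1, 100, "+")])
        models = load_annotation(gtf)
        with pytest.raises(AnnotationError, match="no MANE"):
            select_mane(models, "GENE1")
        dup = models + [models[0]]
        for m in dup:
            m.is_mane_select = True
        with pytest.raises(AnnotationError, match="ambiguous"):
            select_mane(dup, "GENE1")


class TestBuildReference:
    def _host(self):
        gtf = make_gtf([("exon", 1, 60, "+"), ("CDS", 1, 60, "+")]) + make_gtf(
            [("exon", 1, 80, "+"), ("CDS", 21, 60, "+")],
            gene="G2", tx="T2", name="GENE2", seq="chr2",
        )
        seqs = {"chr1": "A" * 60, "chr2": "C" * 80}
        return seqs, load_annotation(gtf)

    def _viral(self, seq_id="vgenome"):
        genes = {
            name: GenomeInterval(seq_id, i * 100, i * 100 + 80)
            for i, name in enumerate(["N", "P", "M", "F", "L"])
        }
        model = ViralGenomeModel(
            seq_id=seq_id, length=500, genes=genes, deleted_genes={"F"}
        )
        return {seq_id: "ACGT" * 125}, model

    def test_model_counts_and_origin(self):
        seqs, annotation = self._host()
        vseqs, vmodel = self._viral()
        ref = build_reference(seqs, annotation, vseqs, vmodel)
        assert len(ref.annotation) == 2 + 5
        assert ref.origin["vgenome"] == "viral"
        assert ref.origin["chr1"] == "host"
        viral_models = [m for m in ref.annotation if ref.origin[m.seq_id] == "viral"]
        assert all(m.utr5 == [] and m.utr3 == [] for m in viral_models)
        assert "F" in ref.viral_model.genes  # retained for coverage reporting
        assert "F" in ref.viral_model.deleted_genes

    def test_collision_namespacing(self):
        seqs, annotation = self._host()
        vseqs, vmodel = self._viral(seq_id="chr1")
        ref = build_reference(seqs, annotation, vseqs, vmodel)
        assert ref.viral_model.seq_id == "viral|chr1"
        assert ref.origin["viral|chr1"] == "viral"
        assert ref.origin["chr1"] == "host"

    def test_host_only(self):
        seqs, annotation = self._host()
        ref = build_reference(seqs, annotation)
        assert ref.viral_model is None
        assert len(ref.annotation) == 2


class TestSequenceExtraction:
    def test_minus_strand_splicing(self):
        seqs = {"c": "AAACCCGGGTTTAAACCC"}
        exons = [GenomeInterval("c", 0, 6, "-"), GenomeInterval("c", 12, 18, "-")]
        model = TranscriptModel("t", "g", "g", exons=exons, cds=exons)
        # transcript = revcomp(AAACCC + AAACCC) = GGGTTTGGGTTT
        assert transcript_sequence(model, seqs) == "GGGTTTGGGTTT"

    def test_reverse_complement(self):
        assert reverse_complement("ACGTN") == "NACGT"
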