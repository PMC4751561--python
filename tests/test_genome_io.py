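"""Transcript-model assembly, region extraction and translation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from uorfscan import genome_io
from uorfscan.genome_io import (
    FastaParseError,
    assemble_transcripts,
    load_assembly,
    translate,
)


class TestLoadAssembly:
    def test_two_contig_toy(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACGTacgt\n>b\nGGG\nCCC\n")
        asm = load_assembly(p)
        assert asm.contig_lengths == {"a": 8, "b": 6}
        assert asm.sequences["a"] == "ACGTACGT"  # lowercase normalized

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="duplicate"):
            load_assembly(p)

    def test_ambiguity_policy(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">a\nACRT\n")
        with pytest.raises(FastaParseError):
            load_assembly(p)
        asm = load_assembly(p, ambiguity="mask")
        assert asm.sequences["a"] == "ACNT"


class TestAssembleTranscripts:
    def test_cds_covers_whole_single_exon(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">c\nATGAAATGA\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "c\tt\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "c\tt\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\tt\texon\t1\t9\t.\t+\t.\tID=t1.e;Parent=t1\n"
            "c\tt\tCDS\t1\t9\t.\t+\t0\tID=t1.c;Parent=t1\n"
        )
        asm = load_assembly(tmp_path / "g.fasta")
        (t,) = assemble_transcripts(asm, tmp_path / "a.gff3")
        assert t.utr5_seq == "" and t.utr3_seq == ""
        assert t.cds_seq == "ATGAAATGA"

    def test_minus_strand_spliced_utr5(self, toy_minus_locus):
        asm = load_assembly(toy_minus_locus["fasta"])
        (t,) = assemble_transcripts(asm, toy_minus_locus["gff3"])
        assert t.strand == "-"
        assert t.utr5_seq == toy_minus_locus["utr5"]
        assert t.cds_seq == toy_minus_locus["cds"]
        assert t.utr3_seq == toy_minus_locus["utr3"]

    def test_mrna_without_cds_skipped(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">c\nATGAAATGA\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "c\tt\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "c\tt\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\tt\texon\t1\t9\t.\t+\t.\tID=t1.e;Parent=t1\n"
        )
        asm = load_assembly(tmp_path / "g.fasta")
        assert assemble_transcripts(asm, tmp_path / "a.gff3") == []

    def test_missing_contig_aborts(self, tmp_path):
        (tmp_path / "g.fasta").write_text(">c\nATGAAATGA\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "d\tt\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "d\tt\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "d\tt\texon\t1\t9\t.\t+\t.\tID=t1.e;Parent=t1\n"
            "d\tt\tCDS\t1\t9\t.\t+\t0\tID=t1.c;Parent=t1\n"
        )
        asm = load_assembly(tmp_path / "g.fasta")
        with pytest.raises(genome_io.AnnotationError, match="contig"):
            assemble_transcripts(asm, tmp_path / "a.gff3")


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,aa",
        [
            ("ATGAAATAA", "MK"),
            ("ATGGCT", "MA"),
            ("ATGGC", "M"),  # trailing partial codon dropped
            ("ATGNNNAAA", "MXK"),
        ],
    )
    def test_examples(self, nt, aa):
        assert translate(nt) == aa

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")

    def test_matches_codon_table_oracle(self, rng):
        table = {}
        for c1 in "ACGT":
            for c2 in "ACGT":
                for c3 in "ACGT":
                    codon = c1 + c2 + c3
                    table[codon] = str(Seq(codon).translate())
        seq = "ATG" + "".join(rng.choice(list("ACGT"), size=297))
        expected = []
        for i in range(0, 300, 3):
            aa = table[seq[i : i + 3]]
            if aa == "*":
                break
            expected.append(aa)
        assert translate(seq) == "".join(expected)


class TestRoundTrip:
    def test_synthetic_regions_recovered_byte_identical(
        self, implanted_dataset, tmp_path
    ):
        paths = implanted_dataset.write(tmp_path / "ds")
        asm = load_assembly(paths["fasta"])
        transcripts = assemble_transcripts(asm, paths["gff3"])
        assert len(transcripts) == len(implanted_dataset.truth)
        for t in transcripts:
            u5, cds, u3 = implanted_dataset.regions[t.transcript_id]
            assert (t.utr5_seq, t.cds_seq, t.utr3_seq) == (u5, cds, u3)

    def test_region_lengths_sum_to_exon_lengths(self, implanted_dataset, tmp_path):
        paths = implanted_dataset.write(tmp_path / "ds")
        asm = load_assembly(paths["fasta"])
        transcripts = assemble_transcripts(asm, paths["gff3"])
        lhs = sum(
            len(t.utr5_seq) + len(t.cds_seq) + len(t.utr3_seq) for t in transcripts
        )
        rhs = sum(e - s for t in transcripts for s, e in t.exons)
        assert lhs == rhs

    def test_transcript_to_genomic_inverts_extraction(self, toy_minus_locus):
        asm = load_assembly(toy_minus_locus["fasta"])
        (t,) = assemble_transcripts(asm, toy_minus_locus["gff3"])
        genome = toy_minus_locus["genome"]
        spliced = t.spliced_seq
        for pos in range(len(spliced)):
            g = t.transcript_to_genomic(pos)
            base = genome[g]
            expected = genome_io.reverse_complement(base) if t.strand == "-" else base
            assert spliced[pos] == expected
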