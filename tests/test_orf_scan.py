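"""uORF/dORF detection, classification and ATG frequency counting."""

import pytest
from hypothesis import given, settings, strategies as st

from uorfscan import orf_scan
from uorfscan.orf_scan import (
    atg_frequencies,
    evaluate_atgs,
    inventory,
    scan_uorf_sequence,
)

from conftest import brute_force_select, brute_force_uorf_scan


class TestScanUorfSequence:
    def test_class1_inframe_no_stop(self):
        res = scan_uorf_sequence("AAATGAAA")
        (rec,) = res.records
        assert (rec.uorf_class, rec.atg_pos, rec.length_codons, rec.frame_offset) == (
            1,
            2,
            2,
            0,
        )
        assert not rec.terminates_in_utr5

    def test_class2_out_of_frame(self):
        res = scan_uorf_sequence("AATGAAAA")
        (rec,) = res.records
        assert (rec.uorf_class, rec.atg_pos, rec.frame_offset) == (2, 1, 1)

    def test_class3_stops_in_utr(self):
        res = scan_uorf_sequence("ATGTAAAAA")
        (rec,) = res.records
        assert (rec.uorf_class, rec.atg_pos, rec.length_codons) == (3, 0, 1)
        assert rec.terminates_in_utr5

    def test_no_atg_empty(self):
        assert scan_uorf_sequence("CCCCCCCC").records == []
        assert scan_uorf_sequence("").records == []

    def test_straddling_atg_excluded(self):
        # ATG whose third base would be the first CDS base is not evaluated
        assert scan_uorf_sequence("CCCCCAT").records == []

    def test_only_five_prime_most_class1_reported(self):
        # two in-frame stop-free ATGs: 5'-most wins, the other is not emitted
        utr5 = "ATGAAAATGAAA"
        res = scan_uorf_sequence(utr5)
        class1 = [r for r in res.records if r.uorf_class == 1]
        assert len(class1) == 1 and class1[0].atg_pos == 0
        assert res.n_class1_candidates == 2

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_matches_brute_force_oracle(self, utr5):
        got = sorted(
            (r.atg_pos, r.uorf_class, r.length_codons, r.frame_offset)
            for r in scan_uorf_sequence(utr5).records
        )
        assert got == brute_force_select(brute_force_uorf_scan(utr5))

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=120))
    def test_every_atg_classified_exactly_once(self, utr5):
        cands = evaluate_atgs(utr5)
        atg_positions = [
            i for i in range(len(utr5) - 2) if utr5[i : i + 3] == "ATG"
        ]
        assert sorted(c[0] for c in cands) == atg_positions
        assert all(c[1] in (1, 2, 3) for c in cands)


class TestDorfScan:
    def test_minimal_dorf(self):
        # scan on a bare sequence via the shared core
        recs = [r for r in evaluate_atgs("ATGTGA") if r[1] == 3]
        assert recs == [(0, 3, 1, 0)]

    def test_open_orf_not_counted_as_dorf(self):
        # ATG without a stop wholly inside the 3'UTR yields no dORF
        assert [r for r in evaluate_atgs("ATGAAAAAA") if r[1] == 3] == []


class TestAtgFrequencies:
    def test_hand_counted_cds_example(self):
        t = atg_frequencies("toy", ["ATGATGATG"], anchor="start")
        assert t.atg_inframe_freq == pytest.approx(2 / 3)
        assert t.atg_outframe_freq == 0.0

    def test_no_atg_zero(self):
        t = atg_frequencies("toy", ["CCCCCC"], anchor="start")
        assert t.atg_inframe_freq == 0.0 and t.atg_outframe_freq == 0.0

    def test_end_anchor_uses_downstream_frame(self):
        # ATG 6 nt before the CDS start: in frame with the CDS
        t = atg_frequencies("toy", ["CATGCC"], anchor="end", exclude_initiator=False)
        assert t.n_inframe == 0 and t.n_outframe == 1
        t2 = atg_frequencies("toy", ["ATGCCC"], anchor="end", exclude_initiator=False)
        assert t2.n_inframe == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            atg_frequencies("toy", [], anchor="start")


class TestInventory:
    def test_partition_sums_to_transcript_count(self, neutral_dataset, tmp_path):
        from uorfscan.genome_io import assemble_transcripts, load_assembly

        paths = neutral_dataset.write(tmp_path / "ds")
        asm = load_assembly(paths["fasta"])
        transcripts = assemble_transcripts(asm, paths["gff3"])
        inv = inventory(transcripts)
        assert inv.partition["n_transcripts"].sum() == inv.n_transcripts
        # class sums must reproduce the presence table's marginals
        for c in (1, 2, 3):
            marginal = inv.partition.loc[
                inv.partition[f"class{c}"], "n_transcripts"
            ].sum()
            assert marginal == inv.class_sums[c]

    def test_all_none_when_no_utr5_atg(self):
        from uorfscan.genome_io import TranscriptModel

        transcripts = [
            TranscriptModel(f"t{i}", f"g{i}", "c", "+", [(0, 30)], [(9, 30)],
                            "CCCCCCCCC", "ATGAAATAAGCCGCCGCCTAA", "")
            for i in range(4)
        ]
        inv = inventory(transcripts)
        assert inv.n_without_uorf == 4
        assert inv.class_sums == {1: 0, 2: 0, 3: 0}
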