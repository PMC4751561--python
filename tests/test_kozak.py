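"""Initiator-context information matrix and Kozak scoring."""

import numpy as np
import pytest

from uorfscan import kozak
from uorfscan.genome_io import assemble_transcripts, load_assembly
from uorfscan.kozak import (
    build_matrix,
    extract_context,
    score_context,
    score_random_contexts,
)


def entropy_oracle(column_freqs):
    """Independent per-position information computation (2 - Shannon H)."""
    h = -sum(p * np.log2(p) for p in column_freqs if p > 0)
    return 2.0 - h


class TestBuildMatrix:
    def test_identical_contexts_give_two_bits_everywhere(self):
        ctx = "C" * 10 + "ATG" + "G" * 6
        m = build_matrix([ctx] * 5)
        assert np.allclose(m.info, 2.0)
        # scoring the training sequence itself: 2 bits at each of 16 positions
        assert score_context(m, ctx) == pytest.approx(32.0)

    def test_two_equiprobable_bases_one_bit(self):
        a = "A" + "C" * 9 + "ATG" + "G" * 6
        b = "T" + "C" * 9 + "ATG" + "G" * 6
        m = build_matrix([a, b])
        assert m.info[0] == pytest.approx(1.0)
        assert np.allclose(m.info[1:10], 2.0)

    def test_uniform_contexts_near_zero_information(self, rng):
        ctxs = [
            "".join(rng.choice(list("ACGT"), 10)) + "ATG" + "".join(rng.choice(list("ACGT"), 6))
            for _ in range(4000)
        ]
        m = build_matrix(ctxs)
        scored = [i for i in range(m.width) if not 10 <= i < 13]
        assert max(m.info[i] for i in scored) < 0.01

    def test_matches_entropy_oracle(self, rng):
        ctxs = [
            "".join(rng.choice(list("ACGT"), p=[0.5, 0.2, 0.2, 0.1], size=10))
            + "ATG"
            + "".join(rng.choice(list("ACGT"), 6))
            for _ in range(500)
        ]
        m = build_matrix(ctxs)
        for i in (0, 5, 15):
            assert m.info[i] == pytest.approx(entropy_oracle(m.freqs[i]), abs=1e-12)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([])

    def test_anchor_must_be_atg(self):
        with pytest.raises(ValueError, match="anchor"):
            build_matrix(["C" * 10 + "AAG" + "G" * 6])


class TestScoreContext:
    def test_toy_matrix_hand_summed(self):
        # 3 training contexts; verify one scored context against hand-summed
        # weights w_i(n) = R_i p_i(n)
        ctxs = [
            "A" + "ATG" + "C",
            "A" + "ATG" + "G",
            "T" + "ATG" + "G",
        ]
        m = build_matrix(ctxs, window_up=1, window_down=1)
        r0 = entropy_oracle([2 / 3, 1 / 3])
        r4 = entropy_oracle([1 / 3, 2 / 3])
        expected = r0 * (2 / 3) + r4 * (1 / 3)  # context "A ATG C"
        assert score_context(m, "AATGC") == pytest.approx(expected)

    def test_n_contributes_zero(self):
        ctx = "C" * 10 + "ATG" + "G" * 6
        m = build_matrix([ctx] * 3)
        with_n = "N" + ctx[1:]
        assert score_context(m, with_n) == pytest.approx(30.0)

    def test_short_context_error_names_missing(self):
        m = build_matrix(["C" * 10 + "ATG" + "G" * 6])
        with pytest.raises(ValueError, match="width"):
            score_context(m, "ATG")


class TestExtractContext:
    def test_overrun_returns_none(self):
        assert extract_context("ATGAAA", 0) is None

    def test_window_shape(self):
        seq = "C" * 10 + "ATG" + "G" * 6
        ctx = extract_context(seq, 10)
        assert ctx == seq and len(ctx) == 19


class TestPopulations:
    def test_reference_scores_beat_random(self, implanted_dataset, tmp_path):
        paths = implanted_dataset.write(tmp_path / "ds")
        asm = load_assembly(paths["fasta"])
        transcripts = assemble_transcripts(asm, paths["gff3"])
        ctxs, _ = kozak.reference_contexts(transcripts)
        m = build_matrix(ctxs)
        ref = kozak.score_population(m, transcripts, "reference")
        rnd = score_random_contexts(m, np.array([0.175, 0.325, 0.325, 0.175]), 5000, 9)
        assert ref.mean > rnd.mean + 2.0

    def test_implanted_translated_contexts_score_high(self, implanted_dataset, tmp_path):
        from uorfscan.orf_scan import scan_uorfs

        paths = implanted_dataset.write(tmp_path / "ds")
        asm = load_assembly(paths["fasta"])
        transcripts = assemble_transcripts(asm, paths["gff3"])
        ctxs, _ = kozak.reference_contexts(transcripts)
        m = build_matrix(ctxs)
        truth = implanted_dataset.truth.set_index("transcript_id")
        tr_scores, ne_scores = [], []
        for t in transcripts:
            for r in scan_uorfs(t):
                if r.uorf_class != 1 or not truth.loc[t.transcript_id, "implanted"]:
                    continue
                ctx = extract_context(t.spliced_seq, r.atg_pos)
                if ctx is None:
                    continue
                (tr_scores if truth.loc[t.transcript_id, "translated"] else ne_scores).append(
                    score_context(m, ctx)
                )
        assert np.mean(tr_scores) > np.mean(ne_scores) + 2.0

    def test_empty_category(self):
        from uorfscan.genome_io import TranscriptModel

        t = TranscriptModel("t", "g", "c", "+", [(0, 40)], [(10, 40)],
                            "C" * 10, "ATG" + "GCC" * 9, "")
        m = build_matrix(["C" * 10 + "ATG" + "G" * 6])
        s = kozak.score_population(m, [t], "class1", [])
        assert len(s.scores) == 0

    def test_random_scores_reproducible_across_seeds(self):
        m = build_matrix(["C" * 10 + "ATG" + "G" * 6, "A" * 10 + "ATG" + "C" * 6] * 10)
        p = np.full(4, 0.25)
        a = score_random_contexts(m, p, 50_000, 1).scores
        b = score_random_contexts(m, p, 50_000, 2).scores
        qa, qb = np.quantile(a, [0.1, 0.5, 0.9]), np.quantile(b, [0.1, 0.5, 0.9])
        assert np.abs(qa - qb).max() < 0.15
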