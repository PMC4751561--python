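"""Alignment backends and the two ortholog-conservation tests."""

from collections import Counter

import numpy as np
import pytest

from uorfscan import conservation
from uorfscan.conservation import (
    AlignerAdapter,
    ProteomeIndex,
    build_extension_queries,
    extension_test,
    first_vs_second_atg_test,
    max_score,
)
from uorfscan.genome_io import TranscriptModel, translate
from uorfscan.orf_scan import UorfRecord
from uorfscan.synthetic_data import generate_ortholog_proteome


def sw_affine_oracle(a, b, sub, open_score=-12, extend_score=-1):
    """Brute-force Gotoh local alignment (affine gaps), raw score.

    First gapped residue scores ``open_score``, each additional one
    ``extend_score`` — the same convention as the production aligner, written
    as an independent three-state dynamic program.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), neg)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i - 1, j - 1] + s, Y[i - 1, j - 1] + s)
            X[i, j] = max(M[i - 1, j] + open_score, X[i - 1, j] + extend_score)
            Y[i, j] = max(M[i, j - 1] + open_score, Y[i, j - 1] + extend_score)
            best = max(best, M[i, j])
    return best


def make_transcript(tid, utr5, cds):
    n = len(utr5) + len(cds)
    return TranscriptModel(tid, tid, "c", "+", [(0, n)], [(len(utr5), n)], utr5, cds, "")


class TestInternalAligner:
    def test_matches_brute_force_dp(self, rng):
        adapter = AlignerAdapter()
        sub = adapter.aligner().substitution_matrix
        alphabet = "ARNDCQEGHKMW"  # reduced alphabet keeps the oracle fast
        for _ in range(120):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(1, 13)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(1, 13)))
            expected = sw_affine_oracle(a, b, sub)
            got = adapter.aligner().score(a, b)
            assert got == pytest.approx(max(expected, 0.0))

    def test_bits_conversion_affine(self):
        adapter = AlignerAdapter()
        assert adapter.bits(0) == 0.0
        assert adapter.bits(-5) == 0.0
        raw = 100.0
        expected = (0.267 * raw - np.log(0.041)) / np.log(2)
        assert adapter.bits(raw) == pytest.approx(expected)


class TestMaxScore:
    def test_self_hit_equals_self_alignment(self):
        adapter = AlignerAdapter()
        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        proteome = {"s1": pep, "s2": "MWWWWHHHHCCCC"}
        raw = adapter.aligner().score(pep, pep)
        assert max_score(pep, proteome, adapter) == pytest.approx(adapter.bits(raw))

    def test_no_shared_kmer_scores_zero(self):
        adapter = AlignerAdapter()
        assert max_score("MKKKKKKKK", {"s": "WWWWWWWWWW"}, adapter) == 0.0

    def test_prefilter_matches_exhaustive_on_hits(self, rng):
        adapter = AlignerAdapter()
        subjects = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
            for i in range(20)
        }
        query = subjects["s3"][10:50]
        filtered = max_score(query, ProteomeIndex(subjects, 5), adapter)
        exhaustive = max_score(query, ProteomeIndex(subjects, None), adapter)
        assert filtered == pytest.approx(exhaustive)

    def test_extension_never_lowers_local_score(self, rng):
        # local alignment: prepending residues cannot lower the best raw score
        adapter = AlignerAdapter(prefilter_k=None)
        subjects = {
            f"s{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))
            for i in range(5)
        }
        for _ in range(10):
            ref = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=40))
            ext = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=10))
            assert max_score(ext + ref, subjects, adapter) >= max_score(
                ref, subjects, adapter
            )

    def test_blastp_backend_smoke(self):
        adapter = AlignerAdapter(backend="blastp")
        pep = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        score = max_score(pep, {"s1": pep}, adapter)
        assert score > 20.0


class TestExtensionQueries:
    def test_concatenation_and_scramble_multiset(self, rng):
        # uORF "ATGAAA|ATG..." -> extension peptide "MK" prepended in frame
        utr5 = "C" * 10 + "ATGAAA"
        cds = "ATGGCTGCTGCTTAA"
        t = make_transcript("t1", utr5, cds)
        u = UorfRecord("t1", 1, 10, 2, 0, False)
        q = build_extension_queries(t, u, seed=4)
        assert q.extension_peptide == "MK"
        assert q.extended == "MK" + q.reference
        assert q.reference == translate(cds)
        assert sorted(q.scrambled1[:2]) == ["K", "M"]
        assert q.scrambled1.endswith(q.reference)

    def test_long_scramble_preserves_residue_multiset(self, rng):
        ext_nt = "ATG" + "".join(
            rng.choice(["GCT", "AAA", "TGG", "CAT", "GAA"], size=29)
        )
        utr5 = "C" * 10 + ext_nt
        cds = "ATGGCTGCTGCTTAA"
        t = make_transcript("t1", utr5, cds)
        u = UorfRecord("t1", 1, 10, 30, 0, False)
        q = build_extension_queries(t, u, seed=1)
        npep = len(q.extension_peptide)
        assert Counter(q.scrambled1[:npep]) == Counter(q.extension_peptide)
        assert Counter(q.scrambled2[:npep]) == Counter(q.extension_peptide)

    def test_non_class1_rejected(self):
        t = make_transcript("t1", "C" * 12, "ATGGCTTAA")
        with pytest.raises(ValueError):
            build_extension_queries(t, UorfRecord("t1", 2, 1, 2, 1, False), 0)


class TestExtensionTest:
    def test_synthetic_recovery_and_null_centering(self, implanted_dataset):
        ds = implanted_dataset
        proteome = generate_ortholog_proteome(ds, seed=55)
        transcripts = []
        records = []
        for _, row in ds.truth.iterrows():
            if not row.implanted:
                continue
            u5, cds, u3 = ds.regions[row.transcript_id]
            t = make_transcript(row.transcript_id, u5, cds)
            transcripts.append(t)
            records.append(
                UorfRecord(row.transcript_id, 1, row.atg_pos, row.ext_codons, 0, False)
            )
        adapter = AlignerAdapter()
        result = extension_test(
            transcripts, records, proteome, adapter, seed=9, quantile=0.5
        )
        conserved = set(
            ds.truth.loc[ds.truth.conserved_extension, "transcript_id"]
        )
        # conserved implants must dominate the top-improvement set
        recall = len(result.high_blastp_ids & conserved) / len(conserved)
        assert recall >= 0.9
        # scrambled-control deltas center at zero on the non-conserved set
        null_deltas = [
            s.delta_scr for s in result.score_sets if s.transcript_id not in conserved
        ]
        assert abs(np.median(null_deltas)) <= 1.0

    def test_no_homologs_no_positive_set(self):
        t = make_transcript("t1", "C" * 10 + "ATGGCTAAA", "ATGCATCATCATTAA")
        u = UorfRecord("t1", 1, 10, 3, 0, False)
        result = extension_test([t], [u], {"s": "WWWWWWWWWW"}, AlignerAdapter(), 0)
        (ss,) = result.score_sets
        assert ss.s_ref == ss.s_ext == 0.0
        assert result.high_blastp_ids == set()


class TestFirstVsSecondAtg:
    def _transcript_with_second_atg(self):
        # peptide: M + 9aa + M + 40aa -> second ATG at aa 10, 40 codons after
        rng = np.random.default_rng(3)
        codons = ["GCT", "GAA", "CAT", "AAA", "TGG", "GTT", "CCT"]
        pep_mid = [str(np.random.default_rng(i).choice(codons)) for i in range(9)]
        tail = [str(rng.choice(codons)) for _ in range(40)]
        cds = "ATG" + "".join(pep_mid) + "ATG" + "".join(tail) + "TAA"
        return make_transcript("t1", "", cds)

    def test_nested_exact_matches(self):
        t = self._transcript_with_second_atg()
        pep = translate(t.cds_seq)
        res = first_vs_second_atg_test([t], {"orth": pep}, AlignerAdapter(), offset_aa=25)
        (r,) = res.records
        assert r.s2 > r.s1 > r.s0
        assert r.precondition_met and r.first_atg_supported

    def test_subject_only_matches_tail(self):
        t = self._transcript_with_second_atg()
        pep = translate(t.cds_seq)
        m = pep.find("M", 1)
        tail_only = pep[m + 25 :]
        res = first_vs_second_atg_test(
            [t], {"orth": tail_only}, AlignerAdapter(), offset_aa=25
        )
        (r,) = res.records
        assert r.s0 == r.s1 == r.s2
        assert not r.precondition_met

    def test_short_cds_excluded_and_counted(self):
        t = make_transcript("t1", "", "ATGGCTATGGCTTAA")  # second ATG, 1 codon after
        res = first_vs_second_atg_test([t], {"s": "MAMA"}, AlignerAdapter(), offset_aa=25)
        assert res.records == [] and res.n_excluded_short == 1
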