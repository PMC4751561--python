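"""Ortholog-proteome alignment tests for uORF translation.

Two tests, both built on maximum local-alignment bit scores against an
ortholog proteome:

* the N-terminal-extension test — does prepending the class-1 uORF peptide to
  the reference peptide improve the best proteome hit more than prepending
  scrambled versions of the same peptide does?
* the first-vs-second-ATG test — among transcripts whose best hit depends on
  sequence right after the second in-frame ATG (S1 > S0), does including the
  segment between the first and second ATG improve the score further
  (S2 > S1)?

The default backend is an internal Smith–Waterman (affine gaps, BLOSUM62)
with bit conversion via Karlin–Altschul parameters, so no external binary is
needed; a blastp subprocess backend reproduces search-tool semantics at
scale. A k-mer seed prefilter (in the spirit of word seeding in search
tools) restricts alignment to subjects sharing at least one exact k-mer with
the query; exhaustive search is available by disabling it.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import TranscriptModel, translate
from .orf_scan import UorfRecord

log = logging.getLogger(__name__)


@dataclass
class AlignerAdapter:
    """Alignment backend configuration; all scores are reported in bits.

    ``gap_open``/``gap_extend`` follow search-tool conventions: a gap of
    length L costs gap_open + L * gap_extend. ``karlin_lambda`` and
    ``karlin_k`` are the gapped Karlin–Altschul parameters for the chosen
    matrix and gap costs (defaults: BLOSUM62, 11/1).
    """

    backend: str = "internal"
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    prefilter_k: int | None = 5

    _aligner: Align.PairwiseAligner | None = field(
        default=None, repr=False, compare=False
    )

    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            a = Align.PairwiseAligner()
            a.mode = "local"
            a.substitution_matrix = substitution_matrices.load(self.matrix)
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            self._aligner = a
        return self._aligner

    def bits(self, raw_score: float) -> float:
        """Karlin–Altschul bit conversion; non-positive raw scores are 'no hit'."""
        if raw_score <= 0:
            return 0.0
        return float(
            (self.karlin_lambda * raw_score - np.log(self.karlin_k)) / np.log(2.0)
        )


class ProteomeIndex:
    """Subject sequences plus an exact k-mer index for seed prefiltering."""

    def __init__(self, sequences: Mapping[str, str], k: int | None = 5):
        if not sequences:
            raise ValueError("proteome is empty")
        self.sequences = dict(sequences)
        self.k = k
        self._index: dict[str, set[str]] = {}
        if k is not None:
            for name, seq in self.sequences.items():
                for i in range(len(seq) - k + 1):
                    self._index.setdefault(seq[i : i + k], set()).add(name)

    def candidates(self, query: str) -> list[str]:
        """Subjects sharing at least one exact k-mer with the query."""
        if self.k is None:
            return list(self.sequences)
        hits: set[str] = set()
        k = self.k
        for i in range(len(query) - k + 1):
            hits |= self._index.get(query[i : i + k], set())
        return sorted(hits)


def max_score(
    query: str, proteome: ProteomeIndex | Mapping[str, str], adapter: AlignerAdapter
) -> float:
    """Maximum bit score of a peptide query over all proteome subjects
    (0 when no subject passes the seed prefilter or no positive alignment)."""
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome, adapter.prefilter_k)
    if adapter.backend == "blastp":
        return _max_scores_blastp({"q": query}, proteome, adapter)["q"]
    aligner = adapter.aligner()
    best = 0.0
    for name in proteome.candidates(query):
        try:
            raw = aligner.score(query, proteome.sequences[name])
        except Exception as exc:  # pragma: no cover - backend diagnostics
            raise RuntimeError(f"alignment backend failed on subject {name}: {exc}")
        if raw > best:
            best = raw
    return adapter.bits(best)


def _max_scores_blastp(
    queries: Mapping[str, str], proteome: ProteomeIndex, adapter: AlignerAdapter
) -> dict[str, float]:
    """Batch maximum bit scores via a local blastp installation."""
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("blastp backend requested but NCBI BLAST+ not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db = tmp / "subjects.faa"
        db.write_text(
            "".join(f">{n}\n{s}\n" for n, s in proteome.sequences.items())
        )
        qf = tmp / "queries.faa"
        qf.write_text("".join(f">{n}\n{s}\n" for n, s in queries.items()))
        subprocess.run(
            ["makeblastdb", "-in", str(db), "-dbtype", "prot"],
            check=True,
            capture_output=True,
        )
        res = subprocess.run(
            [
                "blastp",
                "-query",
                str(qf),
                "-db",
                str(db),
                "-outfmt",
                "6 qseqid bitscore",
                "-comp_based_stats",
                "0",
                "-evalue",
                "1000",
            ],
            check=True,
            capture_output=True,
            text=True,
        )
    best = {name: 0.0 for name in queries}
    for line in res.stdout.splitlines():
        qid, bits = line.split("\t")
        best[qid] = max(best[qid], float(bits))
    return best


@dataclass
class ExtensionQueries:
    """The four peptide queries of the extension test for one transcript."""

    reference: str
    extended: str
    scrambled1: str
    scrambled2: str
    extension_peptide: str


def build_extension_queries(
    t: TranscriptModel, u: UorfRecord, seed: int
) -> ExtensionQueries:
    """Reference peptide, uORF-extended peptide, and two peptide-level
    scrambles of the extension prepended to the unchanged reference."""
    if u.uorf_class != 1:
        raise ValueError("extension queries require a class-1 uORF record")
    ext_nt = t.spliced_seq[u.atg_pos : t.cds_start]
    ext_pep = translate(ext_nt) if len(ext_nt) >= 3 else ""
    if not ext_pep:
        raise ValueError(f"transcript {t.transcript_id}: zero-length extension")
    ref_pep = translate(t.cds_seq)
    rng = np.random.default_rng(seed)
    scr1 = "".join(rng.permutation(list(ext_pep)))
    scr2 = "".join(rng.permutation(list(ext_pep)))
    return ExtensionQueries(
        ref_pep, ext_pep + ref_pep, scr1 + ref_pep, scr2 + ref_pep, ext_pep
    )


@dataclass
class ExtensionScoreSet:
    """Per-transcript bit scores of the extension-conservation test."""

    transcript_id: str
    s_ref: float
    s_ext: float
    s_scr1: float
    s_scr2: float

    @property
    def delta_real(self) -> float:
        return self.s_ext - self.s_ref

    @property
    def delta_scr(self) -> float:
        return max(self.s_scr1, self.s_scr2) - self.s_ref

    @property
    def delta_scr_mean(self) -> float:
        return 0.5 * (self.s_scr1 + self.s_scr2) - self.s_ref

    @property
    def improvement(self) -> float:
        return self.delta_real - max(self.delta_scr, 0.0)


@dataclass
class ExtensionTestResult:
    score_sets: list[ExtensionScoreSet]
    quantile: float
    abs_threshold: float
    high_blastp_ids: set[str]
    high_abs_ids: set[str]

    def improvements(self) -> np.ndarray:
        return np.array([s.improvement for s in self.score_sets])


def extension_test(
    transcripts: Sequence[TranscriptModel],
    class1_records: Sequence[UorfRecord],
    proteome: Mapping[str, str] | ProteomeIndex,
    adapter: AlignerAdapter,
    seed: int,
    quantile: float = 0.25,
    abs_threshold: float = 4.0,
) -> ExtensionTestResult:
    """Run the extension-conservation test over all class-1 transcripts.

    The positive ("high BLASTP") set is the top ``quantile`` fraction by
    sequence-specific improvement; the absolute rule improvement >
    ``abs_threshold`` bits is reported in parallel.
    """
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome, adapter.prefilter_k)
    by_id = {t.transcript_id: t for t in transcripts}
    score_sets: list[ExtensionScoreSet] = []
    if adapter.backend == "blastp":
        queries: dict[str, str] = {}
        order = []
        for i, r in enumerate(class1_records):
            t = by_id[r.transcript_id]
            try:
                q = build_extension_queries(t, r, seed + i)
            except ValueError:
                log.info("skipping %s: empty extension", r.transcript_id)
                continue
            order.append(r.transcript_id)
            queries[f"{r.transcript_id}|ref"] = q.reference
            queries[f"{r.transcript_id}|ext"] = q.extended
            queries[f"{r.transcript_id}|scr1"] = q.scrambled1
            queries[f"{r.transcript_id}|scr2"] = q.scrambled2
        scores = _max_scores_blastp(queries, proteome, adapter)
        for tid in order:
            score_sets.append(
                ExtensionScoreSet(
                    tid,
                    scores[f"{tid}|ref"],
                    scores[f"{tid}|ext"],
                    scores[f"{tid}|scr1"],
                    scores[f"{tid}|scr2"],
                )
            )
    else:
        for i, r in enumerate(class1_records):
            t = by_id[r.transcript_id]
            try:
                q = build_extension_queries(t, r, seed + i)
            except ValueError:
                log.info("skipping %s: empty extension", r.transcript_id)
                continue
            score_sets.append(
                ExtensionScoreSet(
                    r.transcript_id,
                    max_score(q.reference, proteome, adapter),
                    max_score(q.extended, proteome, adapter),
                    max_score(q.scrambled1, proteome, adapter),
                    max_score(q.scrambled2, proteome, adapter),
                )
            )
    high_ids: set[str] = set()
    if score_sets:
        ranked = sorted(score_sets, key=lambda s: s.improvement, reverse=True)
        n_top = max(1, int(round(quantile * len(ranked))))
        high_ids = {s.transcript_id for s in ranked[:n_top] if s.improvement > 0}
    high_abs = {s.transcript_id for s in score_sets if s.improvement > abs_threshold}
    return ExtensionTestResult(score_sets, quantile, abs_threshold, high_ids, high_abs)


@dataclass
class AtgOrderScoreSet:
    """Bit scores of the nested first-vs-second-ATG queries."""

    transcript_id: str
    s0: float
    s1: float
    s2: float

    @property
    def precondition_met(self) -> bool:
        return self.s1 > self.s0

    @property
    def first_atg_supported(self) -> bool:
        return self.s2 > self.s1


@dataclass
class FirstVsSecondResult:
    records: list[AtgOrderScoreSet]
    n_eligible: int
    n_excluded_short: int

    @property
    def n_precondition(self) -> int:
        return sum(r.precondition_met for r in self.records)

    @property
    def fraction_supported(self) -> float:
        met = [r for r in self.records if r.precondition_met]
        if not met:
            return float("nan")
        return sum(r.first_atg_supported for r in met) / len(met)


def first_vs_second_atg_test(
    transcripts: Sequence[TranscriptModel],
    proteome: Mapping[str, str] | ProteomeIndex,
    adapter: AlignerAdapter,
    offset_aa: int = 25,
) -> FirstVsSecondResult:
    """Score the nested queries S0/S1/S2 around the second in-frame ATG.

    S0 aligns from ``offset_aa`` residues C-terminal to the second ATG; S1
    from the second ATG; S2 from the first (reference) ATG. Transcripts whose
    CDS lacks a second in-frame ATG with at least ``offset_aa`` codons after
    it are excluded and counted.
    """
    if not isinstance(proteome, ProteomeIndex):
        proteome = ProteomeIndex(proteome, adapter.prefilter_k)
    records: list[AtgOrderScoreSet] = []
    n_eligible = 0
    n_excluded = 0
    for t in transcripts:
        pep = translate(t.cds_seq)
        m = pep.find("M", 1)
        if m == -1 or len(pep) - (m + offset_aa) < 1:
            n_excluded += 1
            continue
        n_eligible += 1
        q0, q1, q2 = pep[m + offset_aa :], pep[m:], pep
        records.append(
            AtgOrderScoreSet(
                t.transcript_id,
                max_score(q0, proteome, adapter),
                max_score(q1, proteome, adapter),
                max_score(q2, proteome, adapter),
            )
        )
    return FirstVsSecondResult(records, n_eligible, n_excluded)
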