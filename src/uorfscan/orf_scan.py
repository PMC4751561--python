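"""Detection and classification of upstream and downstream open reading frames.

An upstream ORF (uORF) starts at an ATG lying wholly within the annotated
5'UTR. Three classes are distinguished relative to the reference CDS start:

* class 1 — in frame with the CDS, no intervening in-frame stop codon: if
  translated it appends an N-terminal extension to the reference peptide;
* class 2 — out of frame, no stop codon before the CDS start;
* class 3 — the ORF terminates at a stop codon wholly within the 5'UTR.

Per transcript at most one class-1 and one class-2 record are reported (the
5'-most qualifying ATG in each case) while every class-3 ORF is reported
individually. The number of *qualifying candidate* ATGs per class is kept as
well, because the neutral-sequence expectation that out-of-frame candidates
are twice as frequent as in-frame ones is exact for candidate counts but not
for per-transcript presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import TranscriptModel

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class UorfRecord:
    """One detected uORF.

    ``atg_pos`` is the transcript-relative (mRNA-sense, 0-based) position of
    the A of the ATG. For classes 1 and 2 ``length_codons`` counts complete
    codons 5' of the reference CDS start; for class 3 it counts codons before
    the stop (the stop itself excluded).
    """

    transcript_id: str
    uorf_class: int
    atg_pos: int
    length_codons: int
    frame_offset: int
    terminates_in_utr5: bool
    genomic_pos: int | None = None
    strand: str | None = None


@dataclass
class DorfRecord:
    """An ATG-initiated ORF terminating wholly within the 3'UTR."""

    transcript_id: str
    atg_pos: int
    length_codons: int


@dataclass
class ScanResult:
    """Selected records plus per-class candidate ATG counts for one 5'UTR."""

    records: list[UorfRecord]
    n_class1_candidates: int
    n_class2_candidates: int
    n_class3: int


@dataclass
class AtgFrequencyTable:
    """In-frame / out-of-frame ATG frequencies per (total length / 3)."""

    name: str
    atg_inframe_freq: float
    atg_outframe_freq: float
    n_inframe: int
    n_outframe: int
    total_length: int


@dataclass
class OrfInventory:
    """Genome-wide uORF accounting.

    ``partition`` mirrors the 8-way presence-combination table (classes
    present: none / any subset of {1,2,3}); ``class_sums`` count transcripts
    containing at least one uORF of each class; ``candidate_totals`` count
    qualifying ATGs summed over transcripts.
    """

    n_transcripts: int
    presence: pd.DataFrame
    partition: pd.DataFrame
    class_sums: dict[int, int]
    candidate_totals: dict[str, int]

    @property
    def n_without_uorf(self) -> int:
        row = self.partition
        mask = (~row["class1"]) & (~row["class2"]) & (~row["class3"])
        sel = row[mask]
        return int(sel["n_transcripts"].iloc[0]) if len(sel) else 0


def _codon_walk(seq: str, start: int, limit: int) -> int | None:
    """Return the start of the first stop codon in frame from ``start``,
    scanning codons wholly contained in seq[:limit]; None if no stop."""
    for i in range(start, limit - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def evaluate_atgs(utr5: str) -> list[tuple[int, int, int, int]]:
    """Evaluate every ATG wholly within a 5'UTR.

    Returns tuples ``(atg_pos, uorf_class, length_codons, frame_offset)`` for
    each candidate. Class assignment is exhaustive and exclusive: an ATG whose
    in-frame stop lies wholly in the UTR is class 3; otherwise it is a class-1
    candidate (in frame with the downstream CDS) or a class-2 candidate.
    Codons containing N are treated as neither ATG nor stop.
    """
    cds_start = len(utr5)
    out = []
    pos = utr5.find("ATG")
    while pos != -1:
        if pos + 3 <= cds_start:
            stop_at = _codon_walk(utr5, pos + 3, cds_start)
            frame_offset = (cds_start - pos) % 3
            if stop_at is not None:
                out.append((pos, 3, (stop_at - pos) // 3, frame_offset))
            else:
                length = (cds_start - pos) // 3
                out.append((pos, 1 if frame_offset == 0 else 2, length, frame_offset))
        pos = utr5.find("ATG", pos + 1)
    return out


def scan_uorf_sequence(utr5: str) -> ScanResult:
    """Scan one 5'UTR sequence; transcript-agnostic core of :func:`scan_uorfs`."""
    cands = evaluate_atgs(utr5)
    records: list[UorfRecord] = []
    n1 = n2 = n3 = 0
    best1 = best2 = None
    for pos, cls, length, off in cands:
        if cls == 1:
            n1 += 1
            if best1 is None:
                best1 = (pos, length, off)
        elif cls == 2:
            n2 += 1
            if best2 is None:
                best2 = (pos, length, off)
        else:
            n3 += 1
            records.append(
                UorfRecord("", 3, pos, length, off, terminates_in_utr5=True)
            )
    for cls, best in ((1, best1), (2, best2)):
        if best is not None:
            pos, length, off = best
            records.append(
                UorfRecord("", cls, pos, length, off, terminates_in_utr5=False)
            )
    records.sort(key=lambda r: (r.atg_pos, r.uorf_class))
    return ScanResult(records, n1, n2, n3)


def scan_uorfs(t: TranscriptModel) -> list[UorfRecord]:
    """Detect and classify uORFs in a transcript's 5'UTR."""
    result = scan_uorf_sequence(t.utr5_seq)
    for r in result.records:
        r.transcript_id = t.transcript_id
        r.genomic_pos = t.transcript_to_genomic(r.atg_pos)
        r.strand = t.strand
    return result.records


def scan_dorfs(t: TranscriptModel) -> list[DorfRecord]:
    """Detect ATG-initiated ORFs terminating wholly within the 3'UTR."""
    out = []
    for pos, cls, length, _ in evaluate_atgs(t.utr3_seq):
        if cls == 3:
            out.append(DorfRecord(t.transcript_id, pos, length))
    return out


def inventory(
    transcripts: Sequence[TranscriptModel],
    scans: dict[str, ScanResult] | None = None,
) -> OrfInventory:
    """Aggregate per-transcript scans into the presence-combination table."""
    if scans is None:
        scans = {t.transcript_id: scan_uorf_sequence(t.utr5_seq) for t in transcripts}
    rows = []
    cand = {"class1": 0, "class2": 0, "class3": 0}
    for t in transcripts:
        s = scans[t.transcript_id]
        present = {r.uorf_class for r in s.records}
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "class1": 1 in present,
                "class2": 2 in present,
                "class3": 3 in present,
            }
        )
        cand["class1"] += s.n_class1_candidates
        cand["class2"] += s.n_class2_candidates
        cand["class3"] += s.n_class3
    presence = pd.DataFrame(rows).set_index("transcript_id")
    combos = []
    for c1 in (False, True):
        for c2 in (False, True):
            for c3 in (False, True):
                n = int(
                    (
                        (presence["class1"] == c1)
                        & (presence["class2"] == c2)
                        & (presence["class3"] == c3)
                    ).sum()
                )
                combos.append(
                    {"class1": c1, "class2": c2, "class3": c3, "n_transcripts": n}
                )
    partition = pd.DataFrame(combos)
    class_sums = {
        1: int(presence["class1"].sum()),
        2: int(presence["class2"].sum()),
        3: int(presence["class3"].sum()),
    }
    return OrfInventory(
        n_transcripts=len(transcripts),
        presence=presence,
        partition=partition,
        class_sums=class_sums,
        candidate_totals=cand,
    )


def atg_frequencies(
    name: str,
    seqs: Iterable[str],
    anchor: str = "start",
    exclude_initiator: bool = True,
) -> AtgFrequencyTable:
    """Count in-frame / out-of-frame ATGs over a sequence set.

    ``anchor="start"`` fixes the reading frame at position 0 of each sequence
    (CDS sets; the initiator ATG at position 0 is excluded by default);
    ``anchor="end"`` anchors the frame to the downstream CDS start, i.e. a
    position is in frame when its distance to the sequence end is a multiple
    of 3 (5'UTR sets). Frequencies are counts divided by (total length / 3).
    """
    n_in = n_out = total = 0
    any_seq = False
    for seq in seqs:
        any_seq = True
        total += len(seq)
        pos = seq.find("ATG")
        while pos != -1:
            if pos + 3 <= len(seq):
                if anchor == "start":
                    in_frame = pos % 3 == 0
                    if exclude_initiator and pos == 0:
                        pos = seq.find("ATG", pos + 1)
                        continue
                elif anchor == "end":
                    in_frame = (len(seq) - pos) % 3 == 0
                else:
                    raise ValueError(f"unknown anchor {anchor!r}")
                if in_frame:
                    n_in += 1
                else:
                    n_out += 1
            pos = seq.find("ATG", pos + 1)
    if not any_seq or total == 0:
        raise ValueError("sequence set is empty or has zero total length")
    denom = total / 3
    return AtgFrequencyTable(name, n_in / denom, n_out / denom, n_in, n_out, total)


def uorfs_to_frame(records: Iterable[UorfRecord]) -> pd.DataFrame:
    """Tabulate uORF records (one row per uORF) for TSV export."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "uorf_class": r.uorf_class,
                "atg_pos": r.atg_pos,
                "genomic_pos": r.genomic_pos,
                "strand": r.strand,
                "length_codons": r.length_codons,
                "frame_offset": r.frame_offset,
                "terminates_in_utr5": r.terminates_in_utr5,
            }
            for r in records
        ]
    )
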