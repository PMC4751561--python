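"""Genome FASTA / GFF3 ingestion and transcript-model assembly.

Parses a genome assembly and its annotation into :class:`TranscriptModel`
objects carrying spliced, mRNA-sense 5'UTR, CDS and 3'UTR sequences.
Coordinates are stored 0-based half-open internally; GFF3 input/output is
1-based inclusive. Transcripts sharing a gene are treated as independent
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, bad characters)."""


class AnnotationError(ValueError):
    """Raised when GFF3 features are inconsistent with the assembly."""


@dataclass
class GenomeAssembly:
    """A genome as a mapping of contig id to uppercase A/C/G/T/N sequence."""

    sequences: dict[str, str]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the 0-based half-open slice [start, end) of a contig."""
        try:
            seq = self.sequences[contig]
        except KeyError:
            raise AnnotationError(f"contig {contig!r} not present in assembly")
        return seq[start:end]


@dataclass
class TranscriptModel:
    """One annotated transcript with spliced mRNA-sense region sequences.

    ``exons`` and ``cds_intervals`` are sorted genomic 0-based half-open
    intervals. On the minus strand the region sequences are already
    reverse-complemented to mRNA sense, so ``utr5_seq + cds_seq + utr3_seq``
    is the spliced transcript read 5'->3'.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    utr5_seq: str
    cds_seq: str
    utr3_seq: str

    @property
    def spliced_seq(self) -> str:
        return self.utr5_seq + self.cds_seq + self.utr3_seq

    @property
    def cds_start(self) -> int:
        """Transcript coordinate (mRNA sense) of the first CDS base."""
        return len(self.utr5_seq)

    def transcript_to_genomic(self, pos: int) -> int:
        """Map a transcript-relative (mRNA-sense) position to a genomic one."""
        n = sum(e - s for s, e in self.exons)
        if not 0 <= pos < n:
            raise IndexError(f"position {pos} outside transcript of length {n}")
        if self.strand == "-":
            pos = n - 1 - pos  # position along the plus-strand spliced order
        for s, e in self.exons:
            if pos < e - s:
                return s + pos
            pos -= e - s
        raise AssertionError("unreachable")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_assembly(fasta_path: str | Path, ambiguity: str = "error") -> GenomeAssembly:
    """Load a genome FASTA, uppercasing all sequences.

    Parameters
    ----------
    fasta_path:
        Path to a FASTA file.
    ambiguity:
        Policy for IUPAC codes other than A/C/G/T/N: ``"error"`` rejects the
        file, ``"mask"`` replaces them with N.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise FastaParseError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            if ambiguity == "mask":
                table = str.maketrans({c: "N" for c in bad})
                seq = seq.translate(table)
                log.warning("contig %s: masked ambiguity codes %s", rec.id, sorted(bad))
            else:
                raise FastaParseError(
                    f"contig {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
                )
        sequences[rec.id] = seq
    if not sequences:
        raise FastaParseError(f"no FASTA records found in {fasta_path}")
    return GenomeAssembly(sequences)


def spliced_sequence(
    assembly: GenomeAssembly,
    contig: str,
    intervals: Sequence[tuple[int, int]],
    strand: str,
) -> str:
    """Concatenate genomic intervals (sorted by start) and orient to mRNA sense."""
    parts = [assembly.fetch(contig, s, e) for s, e in sorted(intervals)]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def _intervals_contain(outer: list[tuple[int, int]], inner: list[tuple[int, int]]) -> bool:
    return all(any(s >= os and e <= oe for os, oe in outer) for s, e in inner)


def assemble_transcripts(
    assembly: GenomeAssembly, gff3_path: str | Path
) -> list[TranscriptModel]:
    """Build one :class:`TranscriptModel` per mRNA record of a GFF3 file.

    mRNAs without CDS features are skipped with a warning; a CDS interval not
    contained in the transcript's exons raises an error for that transcript
    and processing continues.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[TranscriptModel] = []
    n_skipped_no_cds = 0
    for mrna in db.features_of_type(("mRNA", "transcript")):
        tid = mrna.id
        gene_id = mrna.attributes.get("Parent", [tid])[0]
        if mrna.seqid not in assembly.sequences:
            raise AnnotationError(
                f"mRNA {tid!r} references contig {mrna.seqid!r} absent from assembly"
            )
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not cds:
            log.warning("mRNA %s has no CDS features; skipped", tid)
            n_skipped_no_cds += 1
            continue
        if not exons:
            exons = list(cds)
        if not _intervals_contain(exons, cds):
            log.error("mRNA %s: CDS intervals fall outside exons; transcript dropped", tid)
            continue
        strand = mrna.strand if mrna.strand in "+-" else "+"
        spliced = spliced_sequence(assembly, mrna.seqid, exons, strand)
        # transcript-relative offset of the first CDS base in mRNA sense
        if strand == "+":
            cds_first = min(s for s, _ in cds)
            upstream = sum(min(e, cds_first) - s for s, e in exons if s < cds_first)
        else:
            cds_last = max(e for _, e in cds)
            upstream = sum(e - max(s, cds_last) for s, e in exons if e > cds_last)
        cds_len = sum(e - s for s, e in cds)
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                contig=mrna.seqid,
                strand=strand,
                exons=exons,
                cds_intervals=cds,
                utr5_seq=spliced[:upstream],
                cds_seq=spliced[upstream : upstream + cds_len],
                utr3_seq=spliced[upstream + cds_len :],
            )
        )
    if n_skipped_no_cds:
        log.info("skipped %d mRNAs without CDS", n_skipped_no_cds)
    return models


def translate(cds_seq: str) -> str:
    """Translate a nucleotide sequence with the standard code.

    Stops at the first stop codon; a trailing partial codon is ignored; codons
    containing N translate to X.
    """
    if len(cds_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    trimmed = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def write_region_fasta(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write per-transcript region sequences, ids suffixed .utr5/.cds/.utr3."""
    with open(path, "w") as fh:
        for t in transcripts:
            for suffix, seq in (
                ("utr5", t.utr5_seq),
                ("cds", t.cds_seq),
                ("utr3", t.utr3_seq),
            ):
                if seq:
                    fh.write(f">{t.transcript_id}.{suffix}\n{seq}\n")
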