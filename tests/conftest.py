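"""Shared fixtures: toy loci, synthetic datasets, and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from uorfscan.genome_io import reverse_complement
from uorfscan.synthetic_data import SyntheticSpec, generate_genome

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorf_scan(utr5: str):
    """Naive (start, frame) enumeration oracle for uORF classification.

    Walks every position; an ATG wholly inside the 5'UTR is followed codon by
    codon: a stop wholly inside the UTR makes it class 3, otherwise class 1/2
    by frame against the downstream CDS start. Independent of the scanner's
    single-pass implementation.
    """
    results = []
    n = len(utr5)
    for i in range(n):
        if utr5[i : i + 3] != "ATG" or i + 3 > n:
            continue
        j = i + 3
        cls = None
        while j + 3 <= n:
            if utr5[j : j + 3] in STOPS:
                cls = (3, (j - i) // 3)
                break
            j += 3
        if cls is None:
            frame = (n - i) % 3
            cls = (1 if frame == 0 else 2, (n - i) // 3)
        results.append((i, cls[0], cls[1], (n - i) % 3))
    return results


def brute_force_select(candidates):
    """Apply the reporting rule: all class-3, 5'-most class-1 and class-2."""
    out = [c for c in candidates if c[1] == 3]
    for cls in (1, 2):
        members = [c for c in candidates if c[1] == cls]
        if members:
            out.append(min(members, key=lambda c: c[0]))
    return sorted(out)


def random_utr(rng, length: int, gc: float = 0.65) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def neutral_dataset():
    """A genome with no implanted uORFs: composition-driven uORFs only."""
    spec = SyntheticSpec(n_transcripts=1100, fraction_class1_implanted=0.0)
    return generate_genome(spec, 101)


@pytest.fixture(scope="session")
def implanted_dataset():
    """Half the transcripts carry an implanted class-1 uORF, half of those
    translated/conserved."""
    spec = SyntheticSpec(
        n_transcripts=300, fraction_class1_implanted=1.0, fraction_translated=0.5
    )
    return generate_genome(spec, 202)


@pytest.fixture()
def toy_minus_locus(tmp_path):
    """A 60-nt contig with a two-exon minus-strand transcript whose 5'UTR
    spans the splice junction, plus the hand-derived expected regions."""
    rng = np.random.default_rng(5)
    S = "".join(rng.choice(list("ACGT"), size=60))
    # exons (0-based half-open, genomic): [10,30) and [40,55); CDS [12,27)
    # mRNA sense is the reverse complement, so the 5'UTR is everything
    # genomically right of the CDS: revcomp(S[27:30] + S[40:55]), 18 nt
    expected_utr5 = reverse_complement(S[27:30] + S[40:55])
    expected_cds = reverse_complement(S[12:27])
    expected_utr3 = reverse_complement(S[10:12])
    fasta = tmp_path / "toy.fasta"
    fasta.write_text(f">chr1\n{S}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t11\t55\t.\t-\t.\tID=gene1\n"
        "chr1\ttest\tmRNA\t11\t55\t.\t-\t.\tID=tx1;Parent=gene1\n"
        "chr1\ttest\texon\t11\t30\t.\t-\t.\tID=tx1.e1;Parent=tx1\n"
        "chr1\ttest\texon\t41\t55\t.\t-\t.\tID=tx1.e2;Parent=tx1\n"
        "chr1\ttest\tCDS\t13\t27\t.\t-\t0\tID=tx1.c1;Parent=tx1\n"
    )
    return {
        "fasta": fasta,
        "gff3": gff,
        "genome": S,
        "utr5": expected_utr5,
        "cds": expected_cds,
        "utr3": expected_utr3,
    }
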