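"""Desk-scale synthetic genomes with known uORF ground truth.

The generator emits a multi-contig genome FASTA, a GFF3 annotation of
multi-exon transcripts on both strands, an ortholog proteome, and a
ground-truth table. Background sequence is a zeroth-order model at a
configurable GC content (default 0.65, a strongly GC-rich genome), so uORF
occurrence in unconstrained 5'UTRs is purely composition-driven. A
configurable fraction of transcripts carries an implanted class-1 uORF; a
fraction ``fraction_translated`` of those is "translated": its initiator
context is drawn from a consensus-biased model whose expected Kozak-score
separation from background contexts is ``kozak_effect`` bits, its extension
is longer, and its ortholog retains the (diverged) extension. Reference
initiator ATGs always receive consensus contexts, emulating the selected
context of genuine starts.

Implanted ATGs are guaranteed to be the 5'-most class-1 candidate of their
transcript (competing upstream in-frame ATGs are ablated), so re-scanning
recovers every implant at its recorded position.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome_io import GenomeAssembly, reverse_complement, translate
from .orf_scan import STOP_CODONS, evaluate_atgs

BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# preferred bases of the implanted consensus, scored offsets -10..-1 then +3..+8
CONSENSUS_PREFERRED = "CAAACAAACA" + "GCCGCC"


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic genome."""

    n_transcripts: int = 2000
    gc_content: float = 0.65
    n_contigs: int = 4
    # log-normal length models (natural-log mean / sigma), desk scale
    utr5_log_mean: float = math.log(150.0)
    utr5_log_sigma: float = 0.4
    utr5_min: int = 40
    cds_codons_log_mean: float = math.log(120.0)
    cds_codons_log_sigma: float = 0.5
    cds_codons_min: int = 30
    utr3_log_mean: float = math.log(120.0)
    utr3_log_sigma: float = 0.4
    utr3_min: int = 30
    max_exons: int = 3
    intron_log_mean: float = math.log(150.0)
    intron_log_sigma: float = 0.3
    intron_min: int = 60
    intergenic_len: int = 200
    # uORF implantation
    fraction_class1_implanted: float = 0.5
    fraction_translated: float = 0.5
    kozak_effect: float = 4.0
    translated_ext_log_mean: float = math.log(25.0)
    translated_ext_log_sigma: float = 0.4
    translated_ext_min: int = 4
    neutral_ext_mean_codons: float = 8.0
    # ortholog proteome
    ortholog_conservation: float = 0.7

    def background_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class SyntheticDataset:
    """A generated genome with its annotation and ground truth."""

    spec: SyntheticSpec
    seed: int
    assembly: GenomeAssembly
    gff3: str
    truth: pd.DataFrame
    regions: dict[str, tuple[str, str, str]]
    ref_peptides: dict[str, str]
    ext_peptides: dict[str, str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, ground-truth TSV and a JSON parameter sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff3": outdir / "annotation.gff3",
            "truth": outdir / "ground_truth.tsv",
            "params": outdir / "generation_params.json",
        }
        with open(paths["fasta"], "w") as fh:
            for name, seq in self.assembly.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths["gff3"].write_text(self.gff3)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["params"].write_text(
            json.dumps({"seed": self.seed, **asdict(self.spec)}, indent=2)
        )
        return paths


def consensus_strength(kozak_effect: float, bg_probs: np.ndarray) -> float:
    """Preferred-base probability giving the requested expected Kozak-score
    separation (bits) between consensus-drawn and background-drawn contexts.

    With a per-position profile putting probability p on the preferred base
    (rest uniform), a matrix trained on such draws has information
    R(p) = 2 + p log2 p + (1-p) log2((1-p)/3) and expected score difference
    per position R(p) * (sum_n p_n^2 - sum_n q_n p_n) against background q.
    """

    def separation(p: float) -> float:
        rest = (1.0 - p) / 3.0
        r = 2.0 + p * np.log2(p) + (1.0 - p) * np.log2(rest) if p < 1 else 2.0
        total = 0.0
        for pref in CONSENSUS_PREFERRED:
            q_pref = bg_probs[BASES.index(pref)]
            e_cons = p * p + 3 * rest * rest
            e_bg = q_pref * p + (1.0 - q_pref) * rest
            total += r * (e_cons - e_bg)
        return total

    max_sep = separation(0.999)
    if kozak_effect >= max_sep:
        return 0.999
    return brentq(lambda p: separation(p) - kozak_effect, 0.26, 0.999)


def _draw_background(rng, n: int, p: np.ndarray) -> np.ndarray:
    return rng.choice(np.frombuffer(BASES.encode(), dtype="S1"), size=n, p=p)


def _draw_codons(rng, n_codons: int, p: np.ndarray) -> np.ndarray:
    """Background codons with stop codons rejected by resampling."""
    if n_codons == 0:
        return np.empty(0, dtype="S1")
    arr = _draw_background(rng, 3 * n_codons, p).reshape(n_codons, 3)
    for _ in range(200):
        codons = arr.view("S3").ravel()
        bad = np.array([c.decode() in STOP_CODONS for c in codons])
        if not bad.any():
            return arr.reshape(-1)
        arr[bad] = _draw_background(rng, 3 * int(bad.sum()), p).reshape(-1, 3)
    raise RuntimeError("could not draw stop-free codons (degenerate composition)")


def _consensus_draw(rng, p_pref: float) -> str:
    """One 16-base consensus context draw (offsets -10..-1 and +3..+8)."""
    out = []
    for pref in CONSENSUS_PREFERRED:
        if rng.random() < p_pref:
            out.append(pref)
        else:
            others = [b for b in BASES if b != pref]
            out.append(others[rng.integers(0, 3)])
    return "".join(out)


def _has_frame0_stop(seq: list[str], start: int, end: int, anchor: int) -> bool:
    """Any stop codon in the anchor frame with all 3 bases in [start, end)?"""
    first = start + (anchor - start) % 3
    for i in range(first, end - 2, 3):
        if "".join(seq[i : i + 3]) in STOP_CODONS:
            return True
    return False


def _apply_context(
    rng,
    mrna: list[str],
    atg: int,
    p_pref: float,
    frame_anchor: int,
    keep_open_from: int,
    protected: range | None = None,
) -> None:
    """Overwrite the scored window around ``atg`` with consensus draws.

    Positions in ``protected`` (e.g. an implanted uORF ATG overlapping the
    window) are left untouched. Draws are rejected until no stop codon sits in
    the anchor reading frame among window-overlapping codons at or 3' of
    ``keep_open_from`` — the region where an open reading frame must be
    preserved. Sequence 5' of that bound is unconstrained: rejecting stops
    there would artificially inflate in-frame uORF survival.
    """
    for _ in range(200):
        draw = _consensus_draw(rng, p_pref)
        trial = mrna[:]  # cheap: python list of 1-char strings
        for k, off in enumerate(list(range(-10, 0)) + list(range(3, 9))):
            pos = atg + off
            if protected is not None and pos in protected:
                continue
            trial[pos] = draw[k]
        lo = max(atg - 12, keep_open_from, 0)
        if not _has_frame0_stop(trial, lo, min(atg + 9, len(trial)), frame_anchor):
            mrna[:] = trial
            return
    raise RuntimeError("could not place a stop-free consensus context")


def generate_genome(spec: SyntheticSpec, seed: int) -> SyntheticDataset:
    """Generate a synthetic genome, annotation and ground truth."""
    rng = np.random.default_rng(seed)
    p_bg = spec.background_probs()
    p_pref = consensus_strength(spec.kozak_effect, p_bg)
    stop_list = sorted(STOP_CODONS)
    stop_probs = np.array(
        [np.prod([p_bg[BASES.index(b)] for b in s]) for s in stop_list]
    )
    stop_probs = stop_probs / stop_probs.sum()

    contig_parts: list[list[str]] = [[] for _ in range(spec.n_contigs)]
    contig_len = [0] * spec.n_contigs
    gff_lines = ["##gff-version 3"]
    truth_rows = []
    regions: dict[str, tuple[str, str, str]] = {}
    ref_peptides: dict[str, str] = {}
    ext_peptides: dict[str, str] = {}

    for i in range(spec.n_transcripts):
        tid = f"t{i:05d}"
        gid = f"g{i:05d}"
        u5 = max(spec.utr5_min, int(round(rng.lognormal(spec.utr5_log_mean, spec.utr5_log_sigma))))
        n_c = max(spec.cds_codons_min, int(round(rng.lognormal(spec.cds_codons_log_mean, spec.cds_codons_log_sigma))))
        u3 = max(spec.utr3_min, int(round(rng.lognormal(spec.utr3_log_mean, spec.utr3_log_sigma))))
        implanted = rng.random() < spec.fraction_class1_implanted
        translated = implanted and (rng.random() < spec.fraction_translated)
        ext = 0
        if implanted:
            if translated:
                ext = max(
                    spec.translated_ext_min,
                    int(round(rng.lognormal(spec.translated_ext_log_mean, spec.translated_ext_log_sigma))),
                )
            else:
                ext = 1 + int(rng.geometric(1.0 / spec.neutral_ext_mean_codons))
            u5 = max(u5, 3 * ext + 24)

        utr5 = list(_draw_background(rng, u5, p_bg).tobytes().decode())
        stop = stop_list[rng.choice(3, p=stop_probs)]
        cds = list("ATG") + list(_draw_codons(rng, n_c - 2, p_bg).tobytes().decode()) + list(stop)
        utr3 = list(_draw_background(rng, u3, p_bg).tobytes().decode())
        mrna = utr5 + cds + utr3
        cds_start, cds_end = u5, u5 + 3 * n_c

        atg_pos = -1
        if implanted:
            atg_pos = u5 - 3 * ext
            mrna[atg_pos : atg_pos + 3] = list("ATG")
            if ext > 1:
                body = _draw_codons(rng, ext - 1, p_bg).tobytes().decode()
                mrna[atg_pos + 3 : u5] = list(body)
        # reference initiator always carries a consensus context; an implanted
        # ATG overlapping the window (short extension) is protected, and the
        # ORF must stay open from the implant (or from the CDS when none)
        protected = range(atg_pos, atg_pos + 3) if implanted else None
        open_from = atg_pos if implanted else cds_start
        _apply_context(rng, mrna, cds_start, p_pref, cds_start, open_from, protected)
        if translated:
            _apply_context(rng, mrna, atg_pos, p_pref, cds_start, atg_pos)
        if implanted:
            # ablate any upstream in-frame competitor so the implant is the
            # 5'-most class-1 candidate (each pass destroys one ATG; no base
            # change to C can create a new ATG, so this terminates)
            for _ in range(200):
                extra = [
                    pos
                    for pos, cls, _, _ in evaluate_atgs("".join(mrna[:cds_start]))
                    if cls == 1 and pos < atg_pos
                ]
                if not extra:
                    break
                mrna[extra[0] + 1] = "C"
            else:
                raise RuntimeError(f"{tid}: could not isolate implanted uORF")

        utr5_s = "".join(mrna[:cds_start])
        cds_s = "".join(mrna[cds_start:cds_end])
        utr3_s = "".join(mrna[cds_end:])
        regions[tid] = (utr5_s, cds_s, utr3_s)
        ref_peptides[tid] = translate(cds_s)
        if implanted:
            ext_peptides[tid] = translate(utr5_s[atg_pos:])

        # ---- split into exons, build pre-mRNA and genomic coordinates ----
        m_len = len(mrna)
        n_ex = int(rng.integers(1, spec.max_exons + 1))
        n_ex = min(n_ex, m_len - 1)
        splits = sorted(rng.choice(np.arange(1, m_len), size=n_ex - 1, replace=False)) if n_ex > 1 else []
        bounds = [0] + [int(s) for s in splits] + [m_len]
        pre_parts: list[str] = []
        exon_pre: list[tuple[int, int]] = []  # pre-mRNA coordinates
        off = 0
        for k in range(n_ex):
            ex_seq = "".join(mrna[bounds[k] : bounds[k + 1]])
            pre_parts.append(ex_seq)
            exon_pre.append((off, off + len(ex_seq)))
            off += len(ex_seq)
            if k < n_ex - 1:
                ilen = max(spec.intron_min, int(round(rng.lognormal(spec.intron_log_mean, spec.intron_log_sigma))))
                intron = "GT" + _draw_background(rng, ilen - 4, p_bg).tobytes().decode() + "AG"
                pre_parts.append(intron)
                off += len(intron)
        pre = "".join(pre_parts)
        strand = "+" if rng.random() < 0.5 else "-"

        cidx = i % spec.n_contigs
        spacer = _draw_background(rng, spec.intergenic_len, p_bg).tobytes().decode()
        contig_parts[cidx].append(spacer)
        g_off = contig_len[cidx] + len(spacer)
        segment = pre if strand == "+" else reverse_complement(pre)
        contig_parts[cidx].append(segment)
        contig_len[cidx] = g_off + len(pre)
        contig = f"contig{cidx + 1}"

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            # pre-mRNA [a,b) -> genomic 0-based half-open on the contig
            if strand == "+":
                return g_off + a, g_off + b
            return g_off + len(pre) - b, g_off + len(pre) - a

        exons_g = sorted(to_genomic(a, b) for a, b in exon_pre)
        # CDS pieces: intersect spliced CDS range with exons in transcript order
        cds_pieces_pre: list[tuple[int, int, int]] = []  # (pre_a, pre_b, cum_before)
        spliced_off = 0
        cum = 0
        for a, b in exon_pre:
            ex_len = b - a
            lo = max(cds_start, spliced_off)
            hi = min(cds_end, spliced_off + ex_len)
            if lo < hi:
                cds_pieces_pre.append((a + (lo - spliced_off), a + (hi - spliced_off), cum))
                cum += hi - lo
            spliced_off += ex_len
        gene_a = min(a for a, _ in exons_g)
        gene_b = max(b for _, b in exons_g)
        gff_lines.append(
            f"{contig}\tuorfscan\tgene\t{gene_a + 1}\t{gene_b}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{contig}\tuorfscan\tmRNA\t{gene_a + 1}\t{gene_b}\t.\t{strand}\t.\tID={tid};Parent={gid}"
        )
        for k, (a, b) in enumerate(exons_g):
            gff_lines.append(
                f"{contig}\tuorfscan\texon\t{a + 1}\t{b}\t.\t{strand}\t.\tID={tid}.exon{k + 1};Parent={tid}"
            )
        for k, (a, b, cum_before) in enumerate(cds_pieces_pre):
            ga, gb = to_genomic(a, b)
            phase = (3 - cum_before % 3) % 3
            gff_lines.append(
                f"{contig}\tuorfscan\tCDS\t{ga + 1}\t{gb}\t.\t{strand}\t{phase}\tID={tid}.cds{k + 1};Parent={tid}"
            )
        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gid,
                "contig": contig,
                "strand": strand,
                "implanted": implanted,
                "translated": translated,
                "conserved_extension": translated,
                "atg_pos": atg_pos,
                "ext_codons": ext if implanted else 0,
                "utr5_len": len(utr5_s),
                "cds_codons": n_c,
            }
        )

    sequences = {
        f"contig{k + 1}": "".join(parts) for k, parts in enumerate(contig_parts)
    }
    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        spec,
        seed,
        GenomeAssembly(sequences),
        "\n".join(gff_lines) + "\n",
        truth,
        regions,
        ref_peptides,
        ext_peptides,
    )


def _mutate_peptide(rng, pep: str, identity: float) -> str:
    """Substitute each residue with probability (1 - identity) by a different
    amino acid drawn uniformly."""
    out = list(pep)
    hits = np.nonzero(rng.random(len(out)) < (1.0 - identity))[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "") if out[i] in AMINO_ACIDS else AMINO_ACIDS
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def generate_ortholog_proteome(
    dataset: SyntheticDataset, seed: int, identity: float | None = None
) -> dict[str, str]:
    """One ortholog per transcript at the requested per-residue identity.

    Orthologs of transcripts with a conserved (translated) extension carry the
    equally diverged extension at their N-terminus; all other orthologs are
    the diverged reference peptide only.
    """
    if identity is None:
        identity = dataset.spec.ortholog_conservation
    rng = np.random.default_rng(seed)
    conserved = set(
        dataset.truth.loc[dataset.truth["conserved_extension"], "transcript_id"]
    )
    proteome = {}
    for tid, pep in dataset.ref_peptides.items():
        full = dataset.ext_peptides[tid] + pep if tid in conserved else pep
        proteome[tid + "_ortholog"] = _mutate_peptide(rng, full, identity)
    return proteome


def write_proteome_fasta(proteome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, pep in proteome.items():
            fh.write(f">{name}\n{pep}\n")
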