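"""End-to-end orchestration of the uORF analysis.

Stages run in order: transcript assembly -> uORF/dORF scan and inventory ->
randomized controls -> Kozak matrix and score populations -> mixture
projection of class-1 scores -> conservation tests (when a proteome is
given) -> Bayesian translation-probability table and ROC. Every numeric
output file carries the master seed and a config hash; a single master seed
fans out to per-stage seeds by fixed offsets so stages are individually
re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    conservation,
    distribution_fit,
    genome_io,
    kozak,
    orf_scan,
    seq_controls,
    synthetic_data,
    translation_bayes,
)

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the master seed
SEED_OFFSETS = {
    "synth": 11,
    "proteome": 23,
    "controls": 37,
    "random_scores": 51,
    "conservation": 67,
}


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Exactly one of (``genome_fasta`` + ``gff3``) or ``synthetic`` must be set.
    """

    outdir: str | Path = "uorfscan_out"
    seed: int = 0
    genome_fasta: str | Path | None = None
    gff3: str | Path | None = None
    proteome_fasta: str | Path | None = None
    synthetic: synthetic_data.SyntheticSpec | None = None
    use_synthetic_proteome: bool = True
    kozak_window_up: int = 10
    kozak_window_down: int = 6
    n_random_contexts: int = 20000
    control_replicates: int = 3
    mutagenesis_rates: tuple[float, ...] = (0.1, 0.2, 0.5)
    mixture_bins: int = 40
    high_blastp_quantile: float = 0.25
    improvement_threshold: float = 4.0
    # positive-training-set rule for the Bayes stage: the absolute divergence
    # rule (improvement > threshold bits) tracks the conserved population
    # whatever its prevalence; a fixed quantile miscalibrates the posterior
    # whenever the true translated fraction differs from the quantile
    bayes_positive_rule: str = "absolute"
    bayes_bandwidth: float = 1.5
    bayes_grid: int = 30
    aligner_backend: str = "internal"

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # analysis identity, not output location
        payload = {k: str(v) for k, v in payload.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    outdir: Path
    transcripts: list
    uorfs: list
    inventory: orf_scan.OrfInventory
    matrix: kozak.KozakMatrix | None = None
    score_sets: dict = field(default_factory=dict)
    mixture: distribution_fit.MixtureFit | None = None
    extension: conservation.ExtensionTestResult | None = None
    first_vs_second: conservation.FirstVsSecondResult | None = None
    bayes_model: translation_bayes.BayesModel | None = None
    probability_table: pd.DataFrame | None = None
    roc: translation_bayes.RocCurve | None = None
    truth: pd.DataFrame | None = None


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed} config={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_proteome_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: RunConfig) -> RunResult:
    """Execute the full analysis; returns handles and writes per-stage files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # ---- stage: inputs -------------------------------------------------
    truth = None
    proteome: dict[str, str] | None = None
    if config.synthetic is not None:
        if config.genome_fasta is not None or config.gff3 is not None:
            raise ValueError("give either real input paths or a synthetic spec, not both")
        dataset = synthetic_data.generate_genome(
            config.synthetic, seed + SEED_OFFSETS["synth"]
        )
        dataset.write(outdir / "synthetic_input")
        assembly = dataset.assembly
        gff3_path = outdir / "synthetic_input" / "annotation.gff3"
        truth = dataset.truth
        if config.use_synthetic_proteome:
            proteome = synthetic_data.generate_ortholog_proteome(
                dataset, seed + SEED_OFFSETS["proteome"]
            )
    else:
        if config.genome_fasta is None or config.gff3 is None:
            raise ValueError("genome_fasta and gff3 are required without a synthetic spec")
        assembly = genome_io.load_assembly(config.genome_fasta)
        gff3_path = config.gff3
    if config.proteome_fasta is not None:
        proteome = _load_proteome_fasta(config.proteome_fasta)

    transcripts = genome_io.assemble_transcripts(assembly, gff3_path)
    log.info("stage genome_io: %d transcript models", len(transcripts))

    # ---- stage: ORF scan ----------------------------------------------
    scans = {
        t.transcript_id: orf_scan.scan_uorf_sequence(t.utr5_seq) for t in transcripts
    }
    uorfs: list[orf_scan.UorfRecord] = []
    for t in transcripts:
        for r in scans[t.transcript_id].records:
            r.transcript_id = t.transcript_id
            r.genomic_pos = t.transcript_to_genomic(r.atg_pos)
            r.strand = t.strand
            uorfs.append(r)
    inv = orf_scan.inventory(transcripts, scans)
    dorfs = [d for t in transcripts for d in orf_scan.scan_dorfs(t)]
    _write_tsv(orf_scan.uorfs_to_frame(uorfs), outdir / "uorfs.tsv", config)
    _write_tsv(
        pd.DataFrame([vars(d) for d in dorfs]) if dorfs else pd.DataFrame(),
        outdir / "dorfs.tsv",
        config,
    )
    _write_tsv(inv.partition, outdir / "uorf_class_partition.tsv", config)

    with_utr5 = [t for t in transcripts if t.utr5_seq]
    freq_rows = []
    freq_rows.append(
        vars(orf_scan.atg_frequencies("CDS", (t.cds_seq for t in transcripts), anchor="start"))
    )
    if with_utr5:
        freq_rows.append(
            vars(orf_scan.atg_frequencies("5UT", (t.utr5_seq for t in with_utr5), anchor="end"))
        )
    _write_tsv(pd.DataFrame(freq_rows), outdir / "atg_frequencies.tsv", config)
    log.info(
        "stage orf_scan: %d uORFs, %d dORFs, %d/%d transcripts with 5'UTR",
        len(uorfs),
        len(dorfs),
        len(with_utr5),
        len(transcripts),
    )

    # ---- stage: randomized controls ------------------------------------
    utr5_seqs = [t.utr5_seq for t in with_utr5]
    control_rows = []
    if utr5_seqs:
        nuc = seq_controls.nucleotide_frequencies(utr5_seqs)
        dinuc = seq_controls.dinucleotide_frequencies(utr5_seqs)
        lengths = [len(s) for s in utr5_seqs]
        ctrl_seed = seed + SEED_OFFSETS["controls"]
        genome_lengths = {
            c: [r.length_codons for r in uorfs if r.uorf_class == c] for c in (1, 2, 3)
        }
        kinds: list[tuple[str, seq_controls.ControlSet]] = []
        for rep in range(config.control_replicates):
            s = ctrl_seed + 1000 * rep
            kinds.append(("scramble", seq_controls.scramble_each(utr5_seqs, s, rep)))
            kinds.append(
                ("dinuc_random", seq_controls.random_by_dinucleotide(dinuc, lengths, s + 1, rep))
            )
            for rate in config.mutagenesis_rates:
                kinds.append(
                    (
                        f"mut_{rate}",
                        seq_controls.mutagenize(utr5_seqs, rate, nuc, s + 2, rep),
                    )
                )
        for name, cset in kinds:
            counts = {1: 0, 2: 0, 3: 0}
            lengths_by_class = {1: [], 2: [], 3: []}
            for s_ in cset.sequences:
                res = orf_scan.scan_uorf_sequence(s_)
                for r in res.records:
                    counts[r.uorf_class] += 1
                    lengths_by_class[r.uorf_class].append(r.length_codons)
            for c in (1, 2, 3):
                p_count = distribution_fit.poisson_count_test(
                    len(genome_lengths[c]), counts[c]
                )
                row = {
                    "control": name,
                    "replicate": cset.replicate_index,
                    "uorf_class": c,
                    "n_genome": len(genome_lengths[c]),
                    "n_control": counts[c],
                    "count_p": p_count,
                    "count_stars": distribution_fit.significance_stars(p_count),
                }
                if len(genome_lengths[c]) >= 2 and len(lengths_by_class[c]) >= 2:
                    row["length_ks_p"] = distribution_fit.ks_2sample(
                        genome_lengths[c], lengths_by_class[c]
                    )
                control_rows.append(row)
        _write_tsv(pd.DataFrame(control_rows), outdir / "control_comparison.tsv", config)
        log.info("stage seq_controls: %d control sets", len(kinds))

    # ---- stage: Kozak matrix and score populations ---------------------
    matrix = None
    score_sets: dict[str, kozak.ContextScoreSet] = {}
    mixture = None
    ref_ctx, n_excl = kozak.reference_contexts(
        transcripts, config.kozak_window_up, config.kozak_window_down
    )
    if ref_ctx:
        matrix = kozak.build_matrix(
            ref_ctx, config.kozak_window_up, config.kozak_window_down
        )
        matrix.n_excluded = n_excl
        _write_tsv(matrix.to_frame(), outdir / "kozak_matrix.tsv", config)
        for cat in ("reference", "class1", "class2", "class3", "second_atg"):
            score_sets[cat] = kozak.score_population(matrix, transcripts, cat, uorfs)
        if utr5_seqs:
            score_sets["random"] = kozak.score_random_contexts(
                matrix,
                seq_controls.nucleotide_frequencies(utr5_seqs),
                config.n_random_contexts,
                seed + SEED_OFFSETS["random_scores"],
            )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "category": c,
                        "n": len(s.scores),
                        "n_excluded": s.n_excluded,
                        "mean_bits": s.mean,
                    }
                    for c, s in score_sets.items()
                ]
            ),
            outdir / "kozak_score_summary.tsv",
            config,
        )
        # mixture projection: class-1 scores onto reference + random bases
        if (
            "random" in score_sets
            and len(score_sets["class1"].scores) >= 10
        ):
            lo, hi = distribution_fit.shared_binning(
                score_sets["reference"].scores,
                score_sets["random"].scores,
                score_sets["class1"].scores,
            )
            h_ref = distribution_fit.hist_density(
                score_sets["reference"].scores, config.mixture_bins, (lo, hi)
            )
            h_rand = distribution_fit.hist_density(
                score_sets["random"].scores, config.mixture_bins, (lo, hi)
            )
            h_c1 = distribution_fit.hist_density(
                score_sets["class1"].scores, config.mixture_bins, (lo, hi)
            )
            mixture = distribution_fit.project_mixture(
                h_ref.density, h_rand.density, h_c1.density, ("reference", "random")
            )
            (outdir / "class1_kozak_mixture.json").write_text(
                json.dumps(
                    {
                        "seed": config.seed,
                        "config": config.config_hash(),
                        "weights": {"reference": mixture.c1, "random": mixture.c2},
                        "pve": mixture.pve,
                        "bins": config.mixture_bins,
                        "range": [lo, hi],
                    },
                    indent=2,
                )
            )
        log.info(
            "stage kozak: matrix on %d contexts (%d excluded)", matrix.n_train, n_excl
        )

    # ---- stage: conservation -------------------------------------------
    extension = None
    fvs = None
    class1_records = [r for r in uorfs if r.uorf_class == 1]
    if proteome is not None and class1_records and matrix is not None:
        adapter = conservation.AlignerAdapter(backend=config.aligner_backend)
        index = conservation.ProteomeIndex(proteome, adapter.prefilter_k)
        extension = conservation.extension_test(
            transcripts,
            class1_records,
            index,
            adapter,
            seed + SEED_OFFSETS["conservation"],
            quantile=config.high_blastp_quantile,
            abs_threshold=config.improvement_threshold,
        )
        fvs = conservation.first_vs_second_atg_test(transcripts, index, adapter)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": s.transcript_id,
                        "s_ref": s.s_ref,
                        "s_ext": s.s_ext,
                        "s_scr1": s.s_scr1,
                        "s_scr2": s.s_scr2,
                        "delta_real": s.delta_real,
                        "delta_scr": s.delta_scr,
                        "improvement": s.improvement,
                        "high_blastp": s.transcript_id in extension.high_blastp_ids,
                    }
                    for s in extension.score_sets
                ]
            ),
            outdir / "extension_conservation.tsv",
            config,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "transcript_id": r.transcript_id,
                        "s0": r.s0,
                        "s1": r.s1,
                        "s2": r.s2,
                        "precondition_met": r.precondition_met,
                        "first_atg_supported": r.first_atg_supported,
                    }
                    for r in fvs.records
                ]
            ),
            outdir / "first_vs_second_atg.tsv",
            config,
        )
        log.info(
            "stage conservation: %d class-1 tested, %d high-BLASTP; "
            "precondition %d, supported fraction %.3f",
            len(extension.score_sets),
            len(extension.high_blastp_ids),
            fvs.n_precondition,
            fvs.fraction_supported,
        )
    elif proteome is None:
        log.info("stage conservation skipped: no ortholog proteome provided")

    # ---- stage: Bayesian translation probability -----------------------
    bayes_model = None
    prob_table = None
    roc_curve = None
    if extension is not None and matrix is not None:
        by_id = {t.transcript_id: t for t in transcripts}
        kl1 = []
        for r in class1_records:
            t = by_id[r.transcript_id]
            ctx = kozak.extract_context(
                t.spliced_seq, r.atg_pos, config.kozak_window_up, config.kozak_window_down
            )
            if ctx is None:
                continue
            kl1.append((r.transcript_id, kozak.score_context(matrix, ctx), r.length_codons))
        kl2 = []
        for r in uorfs:
            if r.uorf_class != 2:
                continue
            t = by_id[r.transcript_id]
            ctx = kozak.extract_context(
                t.spliced_seq, r.atg_pos, config.kozak_window_up, config.kozak_window_down
            )
            if ctx is None:
                continue
            kl2.append((kozak.score_context(matrix, ctx), max(r.length_codons, 1)))
        positive_ids = (
            extension.high_abs_ids
            if config.bayes_positive_rule == "absolute"
            else extension.high_blastp_ids
        )
        pos_pairs = np.array(
            [(k, max(l, 1)) for tid, k, l in kl1 if tid in positive_ids]
        )
        neg_pairs = np.array(kl2)
        if len(pos_pairs) >= 20 and len(neg_pairs) >= 20:
            bayes_model = translation_bayes.fit_surfaces(
                pos_pairs,
                neg_pairs,
                translation_bayes.GridConfig(config.bayes_grid, config.bayes_grid),
                bandwidth=config.bayes_bandwidth,
            )
            (outdir / "bayes_model.json").write_text(bayes_model.to_json())
            imps = {s.transcript_id: s.improvement for s in extension.score_sets}
            rows = []
            for tid, k, l in kl1:
                p = float(
                    translation_bayes.posterior(bayes_model, k, max(l, 1))
                )
                rows.append(
                    {
                        "transcript_id": tid,
                        "kozak_score": k,
                        "length_codons": l,
                        "blastp_improvement": imps.get(tid, float("nan")),
                        "high_blastp": tid in extension.high_blastp_ids,
                        "p_translated": p,
                    }
                )
            prob_table = pd.DataFrame(rows)
            _write_tsv(prob_table, outdir / "class1_translation_probability.tsv", config)
            roc_curve = translation_bayes.roc(bayes_model, pos_pairs, neg_pairs)
            _write_tsv(
                pd.DataFrame(
                    {
                        "fpr": roc_curve.fpr,
                        "tpr": roc_curve.tpr,
                        "threshold": roc_curve.thresholds,
                    }
                ),
                outdir / "roc.tsv",
                config,
            )
            log.info(
                "stage bayes: %d class-1 uORFs scored, training AUC %.3f",
                len(rows),
                roc_curve.auc,
            )
        else:
            log.info(
                "stage bayes skipped: training sets too small (%d positive, %d negative)",
                len(pos_pairs),
                len(neg_pairs),
            )

    (outdir / "run_metadata.json").write_text(
        json.dumps(
            {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_transcripts": len(transcripts),
                "n_uorfs": len(uorfs),
                "class_sums": inv.class_sums,
                "candidate_totals": inv.candidate_totals,
            },
            indent=2,
        )
    )
    return RunResult(
        config=config,
        outdir=outdir,
        transcripts=transcripts,
        uorfs=uorfs,
        inventory=inv,
        matrix=matrix,
        score_sets=score_sets,
        mixture=mixture,
        extension=extension,
        first_vs_second=fvs,
        bayes_model=bayes_model,
        probability_table=prob_table,
        roc=roc_curve,
        truth=truth,
    )
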