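"""Test class-1 N-terminal extensions for ortholog conservation.

For each class-1 transcript, aligns four queries against an ortholog
proteome: the reference peptide, the uORF-extended peptide, and two
scrambled-extension controls. A sequence-specific score improvement argues
the extension is translated and under selection.
"""

import numpy as np

from uorfscan.conservation import AlignerAdapter, extension_test
from uorfscan.genome_io import TranscriptModel
from uorfscan.orf_scan import UorfRecord
from uorfscan.synthetic_data import (
    SyntheticSpec,
    generate_genome,
    generate_ortholog_proteome,
)

spec = SyntheticSpec(
    n_transcripts=200, fraction_class1_implanted=1.0, fraction_translated=0.25
)
dataset = generate_genome(spec, seed=7)
proteome = generate_ortholog_proteome(dataset, seed=8)  # 70% residue identity

transcripts, records = [], []
for _, row in dataset.truth.iterrows():
    u5, cds, _ = dataset.regions[row.transcript_id]
    n = len(u5) + len(cds)
    transcripts.append(
        TranscriptModel(row.transcript_id, row.gene_id, "c", "+",
                        [(0, n)], [(len(u5), n)], u5, cds, "")
    )
    records.append(UorfRecord(row.transcript_id, 1, row.atg_pos, row.ext_codons, 0, False))

result = extension_test(
    transcripts, records, proteome, AlignerAdapter(), seed=9, quantile=0.25
)
imps = result.improvements()
conserved = set(dataset.truth.loc[dataset.truth.conserved_extension, "transcript_id"])
recovered = len(result.high_blastp_ids & conserved)
print(f"{len(result.score_sets)} class-1 transcripts tested")
print(f"median improvement (bits): all {np.median(imps):.1f}, "
      f"conserved {np.median([s.improvement for s in result.score_sets if s.transcript_id in conserved]):.1f}")
print(f"top-quantile set recovers {recovered}/{len(conserved)} implanted conserved extensions")
print(f"absolute rule (>4 bits) flags {len(result.high_abs_ids)} transcripts")
# Conserved extensions gain tens of bits over the scrambled controls;
# unconserved ones center at zero improvement.
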