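# Methods

`uorfscan` re-implements, as a reusable library, a genome-wide analysis of
upstream open reading frames (uORFs) in annotated transcriptomes: detection
and classification of 5'UTR ORFs, randomized sequence controls, initiator
context (Kozak) information scoring, linear mixture decomposition of score
distributions, ortholog-proteome conservation tests for N-terminal
extensions, and a two-feature Bayesian estimate of the probability that a
class-1 uORF is translated in vivo. A synthetic-genome generator with known
ground truth supports end-to-end validation of the whole chain.

## Transcript models and uORF classes

Transcripts are assembled from a genome FASTA and a GFF3 annotation
(gene/mRNA/exon/CDS with ID/Parent attributes). GFF3 coordinates are 1-based
inclusive; internally everything is 0-based half-open, and all uORF
coordinates are reported transcript-relative (mRNA sense) with mirrored
genomic positions. Transcripts sharing a gene are processed independently;
mRNAs without CDS are skipped with a warning; a CDS interval outside the
exons drops that transcript and continues. The CDS phase field is trusted
when present; when absent, phase 0 at the first segment is assumed and
logged. Transcripts without an annotated 5'UTR are excluded from 5'UTR
statistics (and counted); how such denominators should be handled is
genuinely underdetermined, so the exclusion counts are always reported.

Every ATG lying wholly within the 5'UTR is evaluated (an ATG straddling the
CDS junction cannot begin a uORF of any class):

* **class 1** — in frame with the reference CDS, no intervening in-frame
  stop: a potential N-terminal extension of the reference peptide;
* **class 2** — out of frame, no stop before the CDS start;
* **class 3** — terminates at a stop wholly inside the 5'UTR.

Per transcript the 5'-most qualifying class-1 and class-2 ATGs are reported
(internal ATGs of that uORF are not emitted as further class-1/2 records,
though they seed class-3 records when their frame stops in the UTR); every
class-3 ORF is an individual record. Class-1/2 lengths count complete codons
5' of the CDS start; class-3 lengths exclude the stop codon. Codons
containing N count as neither ATG nor stop.

Beyond the reported records, the inventory also tracks *candidate* counts:
every ATG that would qualify for a class, with no per-transcript cap. The
neutral-sequence expectation that out-of-frame (class-2) candidates are
twice as frequent as in-frame (class-1) candidates is exact for candidate
counts by frame symmetry. It is **not** exact for per-transcript presence
counts: with at most one record per class per transcript, the expected
presence ratio is 1 + q where q is the probability that a transcript has no
class-1 candidate, which approaches 2 only for rare uORFs. Frame-symmetry
checks therefore use candidate counts.

dORFs (ATG-initiated ORFs terminating wholly within the 3'UTR) are scanned
with the same core in all three frames, each counted separately.

## Randomized controls

Four control constructions isolate sequence-dependent signal from
composition- and length-driven expectation:

* **scramble** — each 5'UTR permuted individually (exact per-sequence
  composition conservation, assertable on every run);
* **dinuc_random** — new sequences from a first-order Markov chain whose
  transitions derive from a target dinucleotide table, lengths matched to
  the source set. Matching is genome-wide (the "5'UT-ome" table), with
  per-sequence matching available by passing per-sequence tables. Note a
  Markov chain can only realize *consistent* tables (row marginals equal to
  column marginals), which empirical tables satisfy up to end effects. An
  exact dinucleotide-preserving shuffle (edge-permutation with walk
  validation) is provided as an alternative mode;
* **mono_random** — the zeroth-order equivalent;
* **mutagenized** — each position independently resampled with probability r
  from the overall nucleotide distribution. Resampling may restore the
  original base, so the realized substitution fraction is r(1 − Σp²) ≈ 0.75r
  for near-uniform compositions; both r and the realized fraction are
  reported.

Three replicates by default, seeds derived from a master seed by fixed
offsets. Count comparisons between genome and control use a z test with
Poisson standard deviations (SD = √n per category) and 0.05/0.01/0.001 star
levels; length distributions are compared by two-sample Kolmogorov–Smirnov.

## Initiator-context (Kozak) scoring

The context matrix is trained on fixed windows around reference initiator
ATGs, by default −10..+8 relative to the A of ATG. The window width is a
modeling choice with no canonical value; it is configurable
(`kozak.window_up` / `window_down`) and carried as metadata on every matrix
and score set, so scores are comparable only within one window setting. Per
position, information is R_i = 2 − H_i bits and the weight of base n is
w_i(n) = R_i p_i(n); a context scores the sum of the weights of its observed
bases. The ATG codon itself is invariant and excluded (it would add a
constant); N contributes 0 bits. No small-sample entropy correction is
applied by default — with thousands of training contexts the bias term
3/(2 ln2 · n) is negligible — but the WebLogo-style correction is available
as a flag. Contexts that would extend 5' of the transcript start are
excluded and counted rather than padded.

Score populations are collected per category: reference initiators, class
1/2/3 uORF ATGs, in-frame CDS-internal ATGs, the first in-frame internal
("second") ATG, and a composition-matched random null (ATG fixed at the
anchor, flanks drawn i.i.d. from a nucleotide composition).

## Mixture decomposition

A target score density C is projected onto two basis densities (columns of
A) by the normal equations [c1 c2] = (AᵀA)⁻¹AᵀC, with the proportion of
variance explained about the target mean as fit quality. The weights are
deliberately unconstrained — this is a linear projection, not an EM mixture
fit — and a [0,1]-bounded variant exists for sensitivity analysis.
Near-collinear bases raise an error reporting the condition number. Default
binning is 40 equal bins over the pooled range (log10 codons for length
mixtures); binning is config-exposed and echoed with every fit. Weight
recovery was validated on constructed mixtures: exact members recover to
1e-10; under multinomial noise at n = 4,000 the mean absolute weight error
stays below 0.03.

The divergence point of two empirical CDFs (used to read off the fraction of
transcripts with sequence-specific conservation signal) is the largest value
at which |CDF₁ − CDF₂| still does not exceed a threshold (default 0.02,
reported with the result).

## Conservation tests

Both tests use maximum local-alignment bit scores against an ortholog
proteome. The default backend is an internal Smith–Waterman (affine gaps,
BLOSUM62, gap open 11 / extend 1) through Biopython's pairwise aligner, with
raw scores converted to bits via gapped Karlin–Altschul parameters
(λ = 0.267, K = 0.041); no external binary is required. A `blastp`
subprocess backend (composition-based statistics off, for score stability)
reproduces search-tool semantics at scale. A k-mer seed prefilter (default
k = 5, exact match) restricts alignment to subjects sharing at least one
word with the query — the same seeding idea BLAST uses; `prefilter_k=None`
is exhaustive. Non-positive raw scores report 0 bits ("no hit"); the maximum
over subjects is taken independently per query, with a same-subject mode for
sensitivity analysis.

**Extension test.** Per class-1 transcript, four queries: the reference
peptide, the uORF-extended peptide, and two peptide-level scrambles of the
extension prepended to the unchanged reference (controls for
simple-sequence score gains). The statistic is
improvement = (s_ext − s_ref) − max(s_scr − s_ref, 0); both the maximum and
the mean of the two scrambled deltas are reported. The "high BLASTP"
positive set has two definitions, both emitted: the top quantile by
improvement (default 0.25) and the absolute divergence rule
improvement > 4 bits.

**First-vs-second-ATG test.** For transcripts with an in-frame internal ATG
at least 25 codons before the CDS end, three nested queries: from 25
residues past the second ATG (S0), from the second ATG (S1), and the full
peptide (S2). Transcripts passing the precondition S1 > S0 have a best hit
that depends on sequence right after the second ATG; among them, S2 > S1
argues the first ATG is genuinely within the CDS.

## Bayesian translation probability

Each class-1 uORF contributes (K bits, L codons). Densities for a positive
training set (conserved class-1 subset) and a negative set (class-2 uORFs)
are estimated on a shared 30×30 grid over (u = 2^K, log10 L), smoothed with
a Gaussian kernel (bandwidth 1.5 cells), floored with a pseudocount of
1/(training count), and normalized. With the 50:50 prior the posterior is
the density ratio f_pos/(f_pos + f_neg); the prior is configurable for
sensitivity analysis. Out-of-grid points clamp to edge cells so every
class-1 uORF receives a probability. Grid ranges default to robust quantiles
(0.5–99.5%) of the pooled training data.

Two estimator choices differ from the most literal reading of the source
analysis, both forced by measurement during development:

* **Score-axis spacing.** With score distributions ~1 bit wide separated by
  several bits, u = 2^K puts the two classes on scales differing by an order
  of magnitude; a strictly u-linear grid then concentrates the negative
  class (and part of the positive) into the bottom cells, and its smoothed
  spike dominates neighbouring cells, miscalibrating posteriors there. The
  default therefore spaces the u edges log-uniformly (uniform in K), a
  monotone reparametrization under which the density ratio is invariant;
  `GridConfig(u_scale="exp2")` restores strictly linear spacing.
* **Positive-set rule.** Training positives default to the absolute
  divergence rule (improvement > 4 bits) rather than a fixed top quantile:
  a fixed quantile trains the positive surface on the longest extensions
  only and miscalibrates the mean posterior whenever the true translated
  prevalence differs from the quantile. The quantile rule remains available
  (`RunConfig.bayes_positive_rule="quantile"`).

The ROC sweeps all distinct posterior values as cutoffs, from +inf (nothing
positive, the (0,0) point) to the minimum (everything positive, (1,1)), with
AUC by trapezoid. On Gaussian training populations d′ apart the machinery
reproduces the closed form AUC = Φ(d′/√2) within 0.02 at n = 5,000, and
leave-half-out retraining moves the AUC by less than 0.05.

## Synthetic genomes

The generator emits FASTA + GFF3 + ortholog proteome + ground truth for
multi-exon transcripts on both strands. Defaults are chosen as the study
conditions and not revisited per run:

| parameter | default | why |
|---|---|---|
| GC content | 0.65 | a strongly GC-rich genome, the regime the analysis targets |
| 5'UTR length | lognormal, median 150 nt | desk-scale but long enough for composition-driven uORFs |
| CDS length | lognormal, median 120 codons | desk-scale; alignment cost grows quadratically |
| 3'UTR length | lognormal, median 120 nt | supports the dORF scan |
| exons | 1–3, introns lognormal median 150 nt | exercises spliced-coordinate arithmetic |
| kozak_effect | 4 bits | expected score separation of consensus vs background contexts; real initiator logos carry a few bits in total, and this keeps the classifier in the regime where the exponentiated-score surface is usable (see above). Fixed analytically: the preferred-base probability solves the separation equation for a matrix trained on the consensus draws themselves |
| translated extension | lognormal, median 25 codons (min 4) | conserved extensions are longer than neutral ones |
| neutral extension | 1 + geometric, mean ≈ 8 codons | composition-like short ORFs |
| ortholog identity | 0.70 per residue | well above the ~50% neutral divergence at which protein similarity disintegrates, i.e. clearly "under selection" |

Reference initiator ATGs always receive consensus-drawn contexts (genuine
starts carry the consensus); implanted "translated" class-1 uORFs receive
the same treatment, while neutral implants keep background contexts.
Stop codons are rejected only where an open frame must be preserved — inside
the CDS-frame region from the implanted ATG (or from the CDS start when
nothing is implanted) — never in unconstrained UTR sequence, which would
artificially inflate in-frame uORF survival. Competing in-frame ATGs 5' of
an implant are ablated (T→C in the ATG; no such substitution can create a
new ATG, so the pass terminates), making every implant the transcript's
5'-most class-1 candidate: re-scanning recovers implants with recall 1.0 by
construction, which the tests assert. Orthologs substitute each residue with
probability 1 − identity by a different amino acid; conserved-extension
orthologs carry the equally diverged extension N-terminally, others omit it.

What the generator does *not* emulate — realistic splice-site sequence,
repeats, codon-usage structure beyond GC, transcript-level expression, UTR
secondary structure, paralogy in the ortholog proteome — bounds what passing
tests show: they validate the statistical machinery end to end under the
stated model, not performance on any real annotation.

## Problem sizes and determinism

Validation runs use 400–3,000 synthetic transcripts per experiment (1,200
for full-pipeline translated-fraction recovery, 3,000 for neutral
frame-symmetry checks, 400 for conservation recovery, 5,000 points per class
for ROC checks) — sizes at which the assertions' tolerances are several sampling
standard errors wide while a full run stays in the minutes range on one
core. A single master seed fans out to per-stage seeds by fixed offsets;
identical configuration and seed reproduce every output byte for byte, and
each output file carries the seed and a configuration hash.

## Known limitations

* Kozak scores are internally consistent but not comparable bit-for-bit
  across window settings or with other tools' scores.
* The internal aligner's bit conversion uses fixed gapped Karlin–Altschul
  parameters; for other matrices or gap costs the constants must be
  supplied. Bit values differ slightly from blastp's (edge corrections,
  rounding), so backends should not be mixed within one analysis.
* The k-mer prefilter can miss subjects whose only similarity to the query
  is gapped at every word; at the identities of interest (≥ 60%) this is
  negligible, and the exhaustive mode exists.
* The posterior is a density-ratio estimate on a finite grid: probabilities
  saturate near the pseudocount floor, and extrapolation beyond the training
  range is clamped, not modeled.
* With at most one class-1/class-2 record per transcript, reported class-2
  records are the maximum over two frames and are therefore slightly longer
  than class-1 records even under neutrality; candidate-level statistics
  avoid this selection effect.
* Candidate ATG counts are clumped within transcripts (a single long
  stop-free stretch contributes several correlated candidates), so their
  seed-to-seed dispersion exceeds the Poisson/binomial idealization by
  roughly a factor of two in standard deviation; occasional genomes land
  outside naive 3-SE bands around the 2:1 frame-symmetry ratio without any
  defect in the scanner.
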