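"""Initiator-context (Kozak-style) information matrix and scoring.

The matrix is trained on fixed-width windows around reference initiator ATGs
(default -10..+8 relative to the A, the invariant ATG codon itself excluded
from scoring). Per position i the information content is R_i = 2 - H_i bits
(H_i the Shannon entropy of the nucleotide frequencies) and the weight of
base n is w_i(n) = R_i * p_i(n). The Kozak score of a context is the sum of
the weights of its observed bases; N contributes 0.

The window width is a modeling choice, so every matrix and score set carries
its window metadata; scores are comparable only within one window setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import TranscriptModel

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class KozakMatrix:
    """Per-position nucleotide information weights around an initiator ATG."""

    window_up: int
    window_down: int
    freqs: np.ndarray      # (width, 4) including the ATG codon rows
    info: np.ndarray       # (width,) bits; ATG rows carry their trained value
    weights: np.ndarray    # (width, 4); ATG codon rows zeroed for scoring
    n_train: int
    n_excluded: int = 0
    small_sample_correction: bool = False

    @property
    def width(self) -> int:
        return self.window_up + 3 + self.window_down

    @property
    def offsets(self) -> list[int]:
        """Offsets relative to the A of ATG for each window column."""
        return list(range(-self.window_up, self.window_down + 3))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.weights, columns=list(BASES))
        df.insert(0, "offset", self.offsets)
        df["info_bits"] = self.info
        return df


@dataclass
class ContextScoreSet:
    """Kozak scores for one category of ATGs (reference, class1, ...)."""

    category: str
    scores: np.ndarray
    n_excluded: int = 0
    window: tuple[int, int] = (10, 6)

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores)) if len(self.scores) else float("nan")


def build_matrix(
    contexts: Sequence[str],
    window_up: int = 10,
    window_down: int = 6,
    small_sample_correction: bool = False,
) -> KozakMatrix:
    """Train an information matrix from same-width initiator contexts.

    Every context must have ATG at the anchor (columns window_up..window_up+2).
    The optional small-sample correction subtracts the WebLogo-style bias term
    (3 / (2 ln 2 n)) from each position's information.
    """
    width = window_up + 3 + window_down
    if not contexts:
        raise ValueError("empty training set")
    counts = np.zeros((width, 4))
    n = 0
    for ctx in contexts:
        if len(ctx) != width:
            raise ValueError(
                f"context length {len(ctx)} does not match window width {width}"
            )
        if ctx[window_up : window_up + 3] != "ATG":
            raise ValueError("context lacks ATG at the anchor position")
        n += 1
        for i, c in enumerate(ctx):
            j = _BASE_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    col_tot = counts.sum(axis=1, keepdims=True)
    col_tot[col_tot == 0] = 1.0
    freqs = counts / col_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        info = np.maximum(info - 3.0 / (2.0 * np.log(2.0) * n), 0.0)
    weights = info[:, None] * freqs
    weights[window_up : window_up + 3] = 0.0  # ATG codon: constant, not scored
    return KozakMatrix(
        window_up,
        window_down,
        freqs,
        info,
        weights,
        n_train=n,
        small_sample_correction=small_sample_correction,
    )


def score_context(m: KozakMatrix, context: str) -> float:
    """Sum of information weights of the observed bases over the window."""
    if len(context) != m.width:
        missing = m.width - len(context)
        raise ValueError(
            f"context width {len(context)} != window width {m.width} "
            f"({missing} positions missing)"
        )
    score = 0.0
    for i, c in enumerate(context):
        j = _BASE_INDEX.get(c)
        if j is not None:
            score += m.weights[i, j]
    return score


def extract_context(
    seq: str, atg_pos: int, window_up: int = 10, window_down: int = 6
) -> str | None:
    """Window around an ATG at ``atg_pos``; None if the window overruns."""
    start = atg_pos - window_up
    end = atg_pos + 3 + window_down
    if start < 0 or end > len(seq):
        return None
    return seq[start:end]


def reference_contexts(
    transcripts: Iterable[TranscriptModel], window_up: int = 10, window_down: int = 6
) -> tuple[list[str], int]:
    """Windows around every reference initiator ATG; overruns excluded/counted."""
    out, excluded = [], 0
    for t in transcripts:
        ctx = extract_context(t.spliced_seq, t.cds_start, window_up, window_down)
        if ctx is None or ctx[window_up : window_up + 3] != "ATG":
            excluded += 1
        else:
            out.append(ctx)
    return out, excluded


def _internal_inframe_atg_positions(t: TranscriptModel) -> list[int]:
    """Transcript positions of in-frame ATG codons inside the CDS (after the
    initiator)."""
    cds = t.cds_seq
    out = []
    for i in range(3, len(cds) - 2, 3):
        if cds[i : i + 3] == "ATG":
            out.append(t.cds_start + i)
    return out


def collect_category_contexts(
    transcripts: Sequence[TranscriptModel],
    category: str,
    uorf_records=None,
    window_up: int = 10,
    window_down: int = 6,
) -> tuple[list[str], int]:
    """Context windows for a named ATG category.

    Categories: ``reference`` (annotated CDS starts), ``class1``/``class2``/
    ``class3`` (uORF ATGs; requires ``uorf_records``), ``internal`` (in-frame
    CDS-internal ATGs), ``second_atg`` (the first in-frame internal ATG only).
    """
    if category == "reference":
        return reference_contexts(transcripts, window_up, window_down)
    by_id = {t.transcript_id: t for t in transcripts}
    out, excluded = [], 0
    if category in ("class1", "class2", "class3"):
        want = int(category[-1])
        if uorf_records is None:
            raise ValueError("uorf_records required for uORF categories")
        for r in uorf_records:
            if r.uorf_class != want:
                continue
            t = by_id[r.transcript_id]
            ctx = extract_context(t.spliced_seq, r.atg_pos, window_up, window_down)
            if ctx is None:
                excluded += 1
            else:
                out.append(ctx)
        return out, excluded
    if category in ("internal", "second_atg"):
        for t in transcripts:
            positions = _internal_inframe_atg_positions(t)
            if category == "second_atg":
                positions = positions[:1]
            for pos in positions:
                ctx = extract_context(t.spliced_seq, pos, window_up, window_down)
                if ctx is None:
                    excluded += 1
                else:
                    out.append(ctx)
        return out, excluded
    raise ValueError(f"unknown category {category!r}")


def score_population(
    m: KozakMatrix,
    transcripts: Sequence[TranscriptModel],
    category: str,
    uorf_records=None,
) -> ContextScoreSet:
    """Score every qualifying ATG of a category; window overruns are excluded
    and counted."""
    contexts, excluded = collect_category_contexts(
        transcripts, category, uorf_records, m.window_up, m.window_down
    )
    scores = np.array([score_context(m, c) for c in contexts])
    return ContextScoreSet(category, scores, excluded, (m.window_up, m.window_down))


def score_random_contexts(
    m: KozakMatrix, nuc_freqs, n: int, seed: int
) -> ContextScoreSet:
    """Scores of random windows drawn i.i.d. from a nucleotide composition,
    with ATG fixed at the anchor (the composition-driven null distribution)."""
    rng = np.random.default_rng(seed)
    p = np.asarray(nuc_freqs, dtype=float)
    p = p / p.sum()
    width = m.width
    draws = rng.choice(4, size=(n, width), p=p)
    # vectorized scoring: gather per-column weights
    w = m.weights
    scores = w[np.arange(width)[None, :], draws].sum(axis=1)
    return ContextScoreSet("random", scores, 0, (m.window_up, m.window_down))
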