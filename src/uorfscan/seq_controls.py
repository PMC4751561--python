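"""Randomized and mutagenized control sequence sets.

Four kinds of controls for separating sequence-dependent signal from
composition- and length-driven expectation:

* ``scramble`` — each sequence individually permuted (exact per-sequence
  composition conservation);
* ``dinuc_random`` — new sequences from a first-order Markov chain matching a
  target dinucleotide frequency table, lengths matched to the source set;
* ``mono_random`` — zeroth-order equivalent (nucleotide frequencies only);
* ``mutagenized`` — each position independently resampled with probability r
  from an overall nucleotide frequency distribution (the resample may restore
  the original base, so the effective substitution rate is r(1 - sum p^2)).

An exact dinucleotide shuffle (edge-permutation with Eulerian-path check) is
provided as an alternative to Markov generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ControlSet:
    """One replicate of a randomized control sequence set."""

    kind: str
    sequences: list[str]
    seed: int
    replicate_index: int = 0
    rate: float | None = None


def nucleotide_frequencies(seqs: Iterable[str]) -> np.ndarray:
    """Overall A/C/G/T frequencies of a sequence set (N ignored)."""
    counts = np.zeros(4)
    for seq in seqs:
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T characters in sequence set")
    return counts / total


def dinucleotide_frequencies(seqs: Iterable[str]) -> np.ndarray:
    """Overall 4x4 dinucleotide frequency table of a sequence set."""
    counts = np.zeros((4, 4))
    for seq in seqs:
        idx = np.fromiter(
            (_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=len(seq)
        )
        a, b = idx[:-1], idx[1:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no dinucleotides in sequence set")
    return counts / total


def scramble_each(seqs: Sequence[str], seed: int, replicate_index: int = 0) -> ControlSet:
    """Permute each sequence individually, preserving its composition exactly."""
    rng = np.random.default_rng(seed)
    out = []
    for seq in seqs:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        out.append(rng.permutation(arr).tobytes().decode())
    return ControlSet("scramble", out, seed, replicate_index)


def _markov_sequences(
    initial: np.ndarray, transition: np.ndarray, lengths: Sequence[int], rng
) -> list[str]:
    cum_t = np.cumsum(transition, axis=1)
    cum_i = np.cumsum(initial)
    out = []
    for n in lengths:
        if n == 0:
            out.append("")
            continue
        u = rng.random(n)
        states = np.empty(n, dtype=np.int64)
        states[0] = np.searchsorted(cum_i, u[0])
        row = cum_t
        for i in range(1, n):
            states[i] = np.searchsorted(row[states[i - 1]], u[i])
        out.append("".join(BASES[s] for s in states))
    return out


def random_by_dinucleotide(
    target_dinuc_freqs: np.ndarray,
    lengths: Sequence[int],
    seed: int,
    replicate_index: int = 0,
) -> ControlSet:
    """Generate sequences from a first-order Markov chain matching a
    dinucleotide frequency table; one sequence per requested length."""
    f = np.asarray(target_dinuc_freqs, dtype=float)
    f = f / f.sum()
    row_sums = f.sum(axis=1)
    transition = np.empty_like(f)
    for i in range(4):
        if row_sums[i] <= 0:
            transition[i] = 0.25  # unreachable state; uniform fallback
        else:
            transition[i] = f[i] / row_sums[i]
    initial = row_sums if row_sums.sum() > 0 else np.full(4, 0.25)
    initial = initial / initial.sum()
    rng = np.random.default_rng(seed)
    seqs = _markov_sequences(initial, transition, lengths, rng)
    return ControlSet("dinuc_random", seqs, seed, replicate_index)


def mono_random(
    target_nuc_freqs: np.ndarray,
    lengths: Sequence[int],
    seed: int,
    replicate_index: int = 0,
) -> ControlSet:
    """Generate i.i.d. sequences with the target nucleotide composition."""
    p = np.asarray(target_nuc_freqs, dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    total = int(sum(lengths))
    flat = rng.choice(np.frombuffer(BASES.encode(), dtype="S1"), size=total, p=p)
    out, off = [], 0
    for n in lengths:
        out.append(flat[off : off + n].tobytes().decode())
        off += n
    return ControlSet("mono_random", out, seed, replicate_index)


def mutagenize(
    seqs: Sequence[str],
    rate: float,
    overall_nuc_freqs: np.ndarray,
    seed: int,
    replicate_index: int = 0,
) -> ControlSet:
    """Resample each position independently with probability ``rate`` from the
    overall nucleotide frequency distribution (original base not excluded)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    p = np.asarray(overall_nuc_freqs, dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    out = []
    for seq in seqs:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        mask = rng.random(len(arr)) < rate
        n_hit = int(mask.sum())
        if n_hit:
            arr[mask] = rng.choice(base_arr, size=n_hit, p=p)
        out.append(arr.tobytes().decode())
    return ControlSet("mutagenized", out, seed, replicate_index, rate=rate)


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Exact dinucleotide-preserving shuffle of one sequence.

    Permutes the multigraph of dinucleotide transitions and accepts the
    permutation when the resulting edge ordering forms a valid walk ending at
    the original terminal base (rejection sampling over edge orderings).
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    for _ in range(1000):
        trial = {a: list(rng.permutation(bs)) for a, bs in edges.items()}
        out = [seq[0]]
        pos = {a: 0 for a in trial}
        cur = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            lst = trial.get(cur)
            if lst is None or pos[cur] >= len(lst):
                ok = False
                break
            nxt = lst[pos[cur]]
            pos[cur] += 1
            out.append(nxt)
            cur = nxt
        if ok and cur == last:
            return "".join(out)
    return seq  # pathological composition; give back the original


def replicates(op, n: int, master_seed: int, **kwargs) -> list[ControlSet]:
    """Run a control-set constructor n times with seeds derived by fixed offsets."""
    return [
        op(seed=master_seed + 1000 * i, replicate_index=i, **kwargs) for i in range(n)
    ]


def write_fasta(controls: ControlSet, path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(controls.sequences):
            fh.write(f">{controls.kind}_rep{controls.replicate_index}_{i}\n{seq}\n")
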