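"""Histogramming, least-squares mixture projection and count/score tests.

The central estimator projects a target density vector C onto the span of two
basis densities (columns of A), solving the normal equations
[c1 c2] = (A'A)^-1 A'C. The weights are deliberately unconstrained — the fit
is a linear projection, not an EM mixture model — and a bound-constrained
variant exists for sensitivity analysis. Quality is summarized as the
proportion of variance explained about the target mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass
class Hist1D:
    edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray


@dataclass
class MixtureFit:
    """Weights and fit quality of a two-component linear projection."""

    basis_labels: tuple[str, str]
    c1: float
    c2: float
    fitted: np.ndarray
    pve: float
    condition_number: float
    constrained: bool = False

    @property
    def weights(self) -> tuple[float, float]:
        return (self.c1, self.c2)


def hist_density(values, bins: int = 40, range_=None) -> Hist1D:
    """Histogram normalized to sum to 1 over the bins."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=bins, range=range_)
    total = counts.sum()
    density = counts / total if total > 0 else counts.astype(float)
    return Hist1D(edges, density, counts)


def shared_binning(*value_sets, bins: int = 40) -> tuple[float, float]:
    """Common (min, max) range spanning several value sets."""
    lo = min(float(np.min(v)) for v in value_sets if len(v))
    hi = max(float(np.max(v)) for v in value_sets if len(v))
    return lo, hi


def project_mixture(
    basis1,
    basis2,
    target,
    labels: tuple[str, str] = ("basis1", "basis2"),
    constrained: bool = False,
    max_condition: float = 1e8,
) -> MixtureFit:
    """Least-squares projection of a target density onto two basis densities.

    All three vectors must share one binning. Raises on (near-)collinear
    bases, reporting the condition number.
    """
    b1 = np.asarray(basis1, dtype=float)
    b2 = np.asarray(basis2, dtype=float)
    c = np.asarray(target, dtype=float)
    if not (b1.shape == b2.shape == c.shape):
        raise ValueError("basis and target vectors must share one binning")
    A = np.column_stack([b1, b2])
    cond = float(np.linalg.cond(A))
    if cond > max_condition:
        raise np.linalg.LinAlgError(
            f"basis vectors are collinear (condition number {cond:.3g})"
        )
    if constrained:
        res = optimize.lsq_linear(A, c, bounds=(0.0, 1.0))
        w = res.x
    else:
        w, *_ = np.linalg.lstsq(A, c, rcond=None)
    fitted = A @ w
    ss_res = float(np.sum((c - fitted) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    pve = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MixtureFit(labels, float(w[0]), float(w[1]), fitted, pve, cond, constrained)


def poisson_count_test(count_a: int, count_b: int) -> float:
    """Two-sided z test for two Poisson-distributed counts (SD = sqrt(n))."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a == 0 and count_b == 0:
        return 1.0
    z = (count_a - count_b) / np.sqrt(count_a + count_b)
    return float(2.0 * stats.norm.sf(abs(z)))


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_t(scores_a, scores_b, alternative: str = "two-sided") -> float:
    """Welch unequal-variance t test p-value.

    ``alternative="greater"`` tests mean(a) > mean(b). Degenerate (zero
    variance) inputs are handled by exact tie logic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 1.0
        if alternative == "two-sided":
            return 0.0
        better = a.mean() > b.mean()
        return 0.0 if (better == (alternative == "greater")) else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.pvalue)


def cumulative_curve(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative fractions (steps of 1/n)."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty value set")
    return v, np.arange(1, len(v) + 1) / len(v)


def divergence_point(
    values_a, values_b, threshold: float = 0.02
) -> tuple[float, float, float]:
    """Where two empirical CDFs first diverge by more than ``threshold``.

    Both CDFs are evaluated on the merged support; returns ``(x, fraction,
    threshold)`` where x is the largest value at which the absolute CDF
    difference still does not exceed the threshold (the last point of
    agreement) and ``fraction`` is CDF_a at that point. Returns
    ``(inf, 1.0, threshold)`` when the curves never diverge.
    """
    a = np.sort(np.asarray(values_a, dtype=float))
    b = np.sort(np.asarray(values_b, dtype=float))
    grid = np.union1d(a, b)
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    diff = np.abs(fa - fb)
    beyond = np.nonzero(diff > threshold)[0]
    if len(beyond) == 0:
        return float("inf"), 1.0, threshold
    first = beyond[0]
    if first == 0:
        return float(grid[0]), 0.0, threshold
    return float(grid[first - 1]), float(fa[first - 1]), threshold


def ks_2sample(values_a, values_b) -> float:
    """Two-sample Kolmogorov–Smirnov p-value."""
    return float(stats.ks_2samp(values_a, values_b).pvalue)
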