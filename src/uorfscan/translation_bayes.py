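"""Two-feature Bayesian translation-probability classifier for class-1 uORFs.

Each uORF is summarized by its Kozak score K (bits) and uORF length L
(codons). Training densities are estimated on a shared 2-D grid over the
exponentiated score u = 2^K and log10 L: lengths are log-transformed because
ORF lengths decay roughly exponentially, and the score axis is laid out in
the exponentiated (probability-like) scale. The positive training set is the
conserved ("high BLASTP") class-1 subset, the negative set the class-2
uORFs, and with a 50:50 prior the posterior reduces to the density ratio

    P(T | K, L) = f_pos(K, L) / (f_pos(K, L) + f_neg(K, L)).

By default the u axis is binned log-uniformly (uniform in K): positive and
negative score distributions have comparable widths in bits but scales
differing by 2^separation in u, so cells linear in u concentrate one class
into a single cell whose smoothed mass then swamps its neighbourhood. The
density ratio is invariant under this monotone reparametrization; a strictly
u-linear grid remains available (``GridConfig(u_scale="exp2")``).

Surfaces are Gaussian-smoothed histograms with a pseudocount floor so the
posterior is defined everywhere; out-of-grid points clamp to edge cells so
every uORF receives a probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class GridConfig:
    """Shared binning for the (2^K, log10 L) plane.

    ``u_scale="bits"`` spaces the score-axis edges log-uniformly in u
    (uniform in K); ``"exp2"`` spaces them linearly in u = 2^K.
    """

    n_u: int = 30
    n_l: int = 30
    u_range: tuple[float, float] | None = None
    l_range: tuple[float, float] | None = None
    u_scale: str = "bits"


@dataclass
class DensitySurface:
    """Normalized, smoothed 2-D density over the (2^K, log10 L) grid."""

    u_edges: np.ndarray
    l_edges: np.ndarray
    density: np.ndarray
    bandwidth: float
    pseudocount: float
    n_train: int


@dataclass
class BayesModel:
    positive: DensitySurface
    negative: DensitySurface
    prior: float = 0.5
    u_scale: str = "bits"

    def to_json(self) -> str:
        return json.dumps(
            {
                "prior": self.prior,
                "u_scale": self.u_scale,
                "bandwidth": self.positive.bandwidth,
                "u_edges": self.positive.u_edges.tolist(),
                "l_edges": self.positive.l_edges.tolist(),
                "positive_density": self.positive.density.tolist(),
                "negative_density": self.negative.density.tolist(),
                "n_train_positive": self.positive.n_train,
                "n_train_negative": self.negative.n_train,
            }
        )


@dataclass
class UorfProbabilityRecord:
    transcript_id: str
    kozak_score: float
    length_codons: int
    p_translated: float


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def transform(K, L) -> tuple[np.ndarray, np.ndarray]:
    """Map (Kozak bits, length codons) to grid coordinates (2^K, log10 L)."""
    K = np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(L < 1):
        raise ValueError("lengths must be >= 1 codon")
    return np.power(2.0, K), np.log10(L)


def _surface(
    u: np.ndarray,
    l: np.ndarray,
    u_edges: np.ndarray,
    l_edges: np.ndarray,
    bandwidth: float,
) -> DensitySurface:
    counts, _, _ = np.histogram2d(
        np.clip(u, u_edges[0], u_edges[-1]),
        np.clip(l, l_edges[0], l_edges[-1]),
        bins=[u_edges, l_edges],
    )
    if bandwidth > 0:
        counts = gaussian_filter(counts, sigma=bandwidth, mode="constant")
    pseudo = 1.0 / max(counts.sum(), 1.0)
    counts = counts + pseudo
    density = counts / counts.sum()
    return DensitySurface(u_edges, l_edges, density, bandwidth, pseudo, len(u))


def fit_surfaces(
    positive_pairs,
    negative_pairs,
    grid: GridConfig | None = None,
    bandwidth: float = 1.5,
    prior: float = 0.5,
    min_train: int = 20,
) -> BayesModel:
    """Fit positive/negative density surfaces on a shared grid.

    ``positive_pairs`` / ``negative_pairs`` are (K, L) arrays of shape (n, 2)
    with K in bits and L in codons. The grid spans the pooled transformed
    range unless explicit ranges are given.
    """
    pos = np.asarray(positive_pairs, dtype=float)
    neg = np.asarray(negative_pairs, dtype=float)
    if len(pos) < min_train or len(neg) < min_train:
        raise ValueError(f"each training set needs at least {min_train} points")
    grid = grid or GridConfig()
    up, lp = transform(pos[:, 0], pos[:, 1])
    un, ln_ = transform(neg[:, 0], neg[:, 1])
    u_all = np.concatenate([up, un])
    l_all = np.concatenate([lp, ln_])
    # robust default ranges: extreme outliers on the exponentiated score axis
    # would otherwise stretch the grid until all central mass shares one cell
    u_range = grid.u_range or (
        float(np.quantile(u_all, 0.005)),
        float(np.quantile(u_all, 0.995)) * 1.0001 + 1e-9,
    )
    l_range = grid.l_range or (
        float(l_all.min()),
        float(l_all.max()) * 1.0001 + 1e-9,
    )
    if grid.u_scale == "bits":
        u_edges = np.power(
            2.0, np.linspace(np.log2(u_range[0]), np.log2(u_range[1]), grid.n_u + 1)
        )
    elif grid.u_scale == "exp2":
        u_edges = np.linspace(u_range[0], u_range[1], grid.n_u + 1)
    else:
        raise ValueError(f"unknown u_scale {grid.u_scale!r}")
    l_edges = np.linspace(l_range[0], l_range[1], grid.n_l + 1)
    p_surface = _surface(up, lp, u_edges, l_edges, bandwidth)
    n_surface = _surface(un, ln_, u_edges, l_edges, bandwidth)
    overlap = np.minimum(p_surface.density, n_surface.density).sum()
    if overlap < 1e-6:
        import logging

        logging.getLogger(__name__).warning(
            "training surfaces have essentially disjoint support; posterior saturates"
        )
    return BayesModel(p_surface, n_surface, prior, grid.u_scale)


def _cell_indices(surface: DensitySurface, u, l) -> tuple[np.ndarray, np.ndarray]:
    iu = np.clip(
        np.searchsorted(surface.u_edges, u, side="right") - 1,
        0,
        surface.density.shape[0] - 1,
    )
    il = np.clip(
        np.searchsorted(surface.l_edges, l, side="right") - 1,
        0,
        surface.density.shape[1] - 1,
    )
    return iu, il


def posterior(model: BayesModel, K, L) -> np.ndarray:
    """Posterior probability of translation at (K bits, L codons); vectorized.

    Out-of-grid points are clamped to the nearest edge cell.
    """
    u, l = transform(K, L)
    iu, il = _cell_indices(model.positive, u, l)
    fp = model.positive.density[iu, il]
    fn = model.negative.density[iu, il]
    pt = model.prior
    return (fp * pt) / (fp * pt + fn * (1.0 - pt))


def roc(model: BayesModel, positive_pairs, negative_pairs) -> RocCurve:
    """ROC of the posterior over labelled (K, L) sets; AUC by trapezoid."""
    pos = np.asarray(positive_pairs, dtype=float)
    neg = np.asarray(negative_pairs, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("positive and negative sets must be non-empty")
    sp = posterior(model, pos[:, 0], pos[:, 1])
    sn = posterior(model, neg[:, 0], neg[:, 1])
    # sweep cutoffs from +inf (nothing called positive) down to the minimum
    # observed posterior (everything positive): endpoints (0,0) and (1,1)
    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([sp, sn]))[::-1]])
    tpr = np.array([(sp >= t).mean() for t in thresholds])
    fpr = np.array([(sn >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thresholds, auc)
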