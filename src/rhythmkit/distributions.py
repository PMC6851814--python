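"""Log inter-event-interval distributions and their comparison.

Timing of an event series is characterized as the distribution of the
base-10 logarithm of its inter-event intervals (log-IEI), binned on a grid
shared across all series being compared.  Distributions are compared with
the symmetric Kullback-Leibler divergence (sum of the two directed
divergences, in nats; zero only for identical distributions), assembled
into a distance matrix, and embedded in two dimensions with metric
multidimensional scaling — only the inter-point distances in the embedding
are meaningful, not the axes.

Order of intervals is irrelevant throughout: shuffling the IEIs of a
series leaves its distribution, hence every distance, unchanged.  The
price of this simplicity is insensitivity to higher-order temporal
structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.manifold import smacof

from .events import IntervalSequence

__all__ = [
    "LogIEIDistribution",
    "DistanceMatrix",
    "Embedding2D",
    "log_iei_distribution",
    "count_modes",
    "skl_divergence",
    "pairwise_distances",
    "mds_embed",
]

DEFAULT_N_BINS = 30
DEFAULT_SMOOTHING = 0.5  # Jeffreys-style pseudo-count per bin


@dataclass(frozen=True)
class LogIEIDistribution:
    """Binned probability distribution of log10 inter-event intervals."""

    bin_edges: np.ndarray  # log10-seconds, uniform width, length n_bins+1
    probs: np.ndarray  # sums to 1; strictly positive after smoothing
    n_intervals: int
    smoothing: float
    label: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, float)
        probs = np.asarray(self.probs, float)
        if edges.size != probs.size + 1:
            raise ValueError("bin_edges must have one more entry than probs")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bin_edges must be strictly increasing and uniform")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probs", probs)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mode_interval(self) -> float:
        """Interval (seconds) at the highest-probability bin center."""
        return float(10.0 ** self.bin_centers[int(np.argmax(self.probs))])

    def same_grid(self, other: "LogIEIDistribution") -> bool:
        return self.bin_edges.size == other.bin_edges.size and np.allclose(
            self.bin_edges, other.bin_edges, rtol=0, atol=1e-12
        )


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(d, d.T, atol=1e-12) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_unique(self) -> int:
        """Number of unique off-diagonal distances, n(n-1)/2."""
        n = len(self.labels)
        return n * (n - 1) // 2

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), 1)
        return self.d[iu]


@dataclass(frozen=True)
class Embedding2D:
    labels: tuple
    points: np.ndarray  # (n, 2)
    stress: float  # normalized Kruskal stress-1
    seed: int


def _positive_values(seq: IntervalSequence | np.ndarray) -> np.ndarray:
    if isinstance(seq, IntervalSequence):
        vals = seq.values
    else:
        vals = np.asarray(seq, float)
    if np.any(vals <= 0):
        raise ValueError(
            "non-positive interval reached log-IEI construction; "
            "filter overlap-flagged intervals upstream"
        )
    return vals


def log_iei_distribution(
    intervals: IntervalSequence | np.ndarray | Sequence[IntervalSequence],
    n_bins: int = DEFAULT_N_BINS,
    range: Optional[tuple[float, float]] = None,
    smoothing: float = DEFAULT_SMOOTHING,
    labels: Optional[Sequence[str]] = None,
) -> "LogIEIDistribution | list[LogIEIDistribution]":
    """Histogram log10 intervals on a shared uniform grid and normalize.

    Given several interval sequences, one bin grid spanning the *pooled*
    log10 range is used for all of them (required for divergences).  A
    pseudo-count ``smoothing`` is added to every bin before normalization
    so every bin probability is strictly positive and KL terms are finite.
    `range` is a (lo, hi) pair in log10-seconds overriding the pooled range.
    """
    single = isinstance(intervals, (IntervalSequence, np.ndarray)) or (
        len(intervals) > 0 and np.isscalar(intervals[0])
    )
    seqs = [intervals] if single else list(intervals)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    log_vals = [np.log10(_positive_values(s)) for s in seqs]
    if range is None:
        lo = min(v.min() for v in log_vals)
        hi = max(v.max() for v in log_vals)
        if hi - lo < 1e-9:  # degenerate: all intervals identical
            # span 0.1 dex with the common value at a bin *center*
            mid, w = 0.5 * (lo + hi), 0.1 / n_bins
            lo = mid - 0.05 - w / 2
            hi = lo + 0.1
        else:
            pad = 0.5 * (hi - lo) / n_bins
            lo, hi = lo - pad, hi + pad
    else:
        lo, hi = range
    edges = np.linspace(lo, hi, n_bins + 1)
    out = []
    for i, v in enumerate(log_vals):
        counts, _ = np.histogram(v, bins=edges)
        probs = counts + smoothing
        probs = probs / probs.sum()
        if labels is not None:
            label = labels[i]
        elif isinstance(seqs[i], IntervalSequence):
            label = seqs[i].label
        else:
            label = ""
        out.append(
            LogIEIDistribution(edges, probs, n_intervals=int(v.size), smoothing=smoothing, label=label)
        )
    return out[0] if single else out


def count_modes(p: LogIEIDistribution, min_prominence: float = 0.05) -> int:
    """Number of local maxima of the bin probabilities whose prominence is
    at least ``min_prominence`` times the maximum bin probability.

    Boundary bins can be modes (the probability vector is zero-padded at
    both ends before peak finding).
    """
    padded = np.concatenate([[0.0], p.probs, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * p.probs.max())
    return int(peaks.size)


def mode_locations(p: LogIEIDistribution, min_prominence: float = 0.05) -> np.ndarray:
    """Interval values (seconds) at the prominent modes, ascending."""
    padded = np.concatenate([[0.0], p.probs, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * p.probs.max())
    return 10.0 ** p.bin_centers[peaks - 1]


def skl_divergence(p: LogIEIDistribution, q: LogIEIDistribution) -> float:
    """Symmetric KL divergence KL(p||q) + KL(q||p), in nats.

    Requires identical bin grids (rebuild on a shared grid otherwise) and
    strictly positive probabilities, which smoothing guarantees.
    """
    if not p.same_grid(q):
        raise ValueError("distributions are on different bin grids; rebuild on a shared grid")
    pp, qq = p.probs, q.probs
    if np.any(pp <= 0) or np.any(qq <= 0):
        raise ValueError("probabilities must be strictly positive (use smoothing > 0)")
    return float(np.sum(pp * np.log(pp / qq)) + np.sum(qq * np.log(qq / pp)))


def pairwise_distances(dists: Sequence[LogIEIDistribution]) -> DistanceMatrix:
    """Full symmetric matrix of sKL divergences between distributions.

    All inputs must share one bin grid and carry unique labels.
    """
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions")
    labels = [d.label for d in dists]
    if len(set(labels)) != len(labels):
        raise ValueError("distribution labels must be unique")
    n = len(dists)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = skl_divergence(dists[i], dists[j])
    return DistanceMatrix(tuple(labels), d)


def _classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical scaling: deterministic initialization for SMACOF."""
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def mds_embed(d: DistanceMatrix, seed: int = 0) -> Embedding2D:
    """Metric MDS of an sKL distance matrix into the plane.

    SMACOF stress minimization started from the classical-scaling solution
    (deterministic; the seed covers the degenerate fallback).  The reported
    stress is the normalized Kruskal stress-1,
    ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)``, zero for perfectly
    embeddable inputs.
    """
    mat = d.d
    if np.all(mat == 0):
        n = len(d.labels)
        return Embedding2D(d.labels, np.zeros((n, 2)), 0.0, seed)
    init = _classical_mds(mat)
    points, raw_stress = smacof(
        mat,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=300,
        eps=1e-9,
        random_state=seed,
        normalized_stress=False,
    )
    denom = np.sum(d.condensed() ** 2)
    stress1 = float(np.sqrt(raw_stress / denom)) if denom > 0 else 0.0
    return Embedding2D(d.labels, points, stress1, seed)
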