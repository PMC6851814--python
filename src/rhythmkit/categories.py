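"""Durational categories and their transition structure.

Many vocal repertoires use a small set of discrete duration "categories":
the duration (or interval) distribution is multimodal, and each mode
approximates the prototype of one category.  This module detects such
categories by fitting Gaussian mixtures to log10 durations and selecting
the number of components by BIC, then summarizes sequential structure as a
row-stochastic transition matrix P(next category | current category) —
values concentrated on the diagonal indicate same-category persistence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

from .events import EventSeries, IntervalConvention, intervals

__all__ = [
    "CategoryModel",
    "TransitionMatrix",
    "detect_duration_categories",
    "transition_matrix",
    "category_pipeline",
]


@dataclass(frozen=True)
class CategoryModel:
    """BIC-selected Gaussian-mixture model of log10 durations.

    Centroids are reported back on the seconds scale (``10**mean``) and
    sorted ascending so that fitted models are comparable; component order
    of weights/sds/assignment follows the sorted centroids.
    """

    k: int
    centroids: np.ndarray  # seconds, strictly increasing
    weights: np.ndarray
    sds: np.ndarray  # log10-duration scale
    assignment: np.ndarray  # category index per input duration
    bic: float
    bic_by_k: Optional[dict] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.centroids) <= 0):
            raise ValueError("centroids must be strictly increasing")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic category transition probabilities with raw counts.

    Rows with no observed transitions are left all-zero and listed in
    ``empty_rows``.
    """

    k: int
    p: np.ndarray
    counts: np.ndarray
    empty_rows: tuple = ()

    def __post_init__(self) -> None:
        if self.p.shape != (self.k, self.k) or self.counts.shape != (self.k, self.k):
            raise ValueError("p and counts must be KxK")
        row_sums = self.p.sum(axis=1)
        observed = self.counts.sum(axis=1) > 0
        if np.any(np.abs(row_sums[observed] - 1.0) > 1e-12) or np.any(self.p < 0):
            raise ValueError("observed rows must be non-negative and sum to 1")


def detect_duration_categories(
    durations: np.ndarray,
    k_max: int = 6,
    seed: int = 0,
    reg_covar: float = 1e-6,
) -> CategoryModel:
    """Fit Gaussian mixtures on log10(durations) for k = 1..k_max, keep the
    minimum-BIC model (ties broken toward smaller k), and assign every
    duration to its maximum-responsibility component.

    ``reg_covar`` is the variance floor guarding against degenerate
    components on (near-)duplicated data.
    """
    durations = np.asarray(durations, float)
    if durations.size < 10:
        raise ValueError("need at least 10 durations")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.log10(durations).reshape(-1, 1)
    best = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=reg_covar,
                random_state=seed,
                n_init=3,
            ).fit(x)
        bic = gm.bic(x)
        bic_by_k[k] = float(bic)
        if best is None or bic < best[0] - 1e-9:  # strict: ties favor smaller k
            best = (bic, k, gm)
    bic, k, gm = best
    means = gm.means_.ravel()
    order = np.argsort(means)
    raw_assign = gm.predict(x)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return CategoryModel(
        k=k,
        centroids=10.0 ** means[order],
        weights=gm.weights_[order],
        sds=np.sqrt(gm.covariances_.reshape(k)[order]),
        assignment=remap[raw_assign],
        bic=float(bic),
        bic_by_k=bic_by_k,
    )


def transition_matrix(labels: np.ndarray, k: int) -> TransitionMatrix:
    """Maximum-likelihood transition probabilities from a label sequence.

    ``counts[a, b]`` is the number of i with ``labels[i] = a`` followed by
    ``labels[i+1] = b``; ``p`` is the row-normalized counts (no smoothing).
    """
    labels = np.asarray(labels, int)
    if labels.size < 2:
        raise ValueError("need at least 2 labels")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1)
    row_sums = counts.sum(axis=1)
    p = np.zeros_like(counts)
    observed = row_sums > 0
    p[observed] = counts[observed] / row_sums[observed, None]
    empty = tuple(int(i) for i in np.flatnonzero(~observed))
    return TransitionMatrix(k=k, p=p, counts=counts, empty_rows=empty)


def category_pipeline(
    events: EventSeries,
    use: str = "intervals",
    k_max: int = 6,
    seed: int = 0,
) -> tuple[CategoryModel, TransitionMatrix]:
    """Detect categories on call durations or inter-onset intervals and
    estimate their transition matrix.

    The diagonal of the returned matrix quantifies same-category
    persistence (how often a duration is followed by another of the same
    category).
    """
    if use == "durations":
        if events.durations is None:
            raise ValueError("use='durations' requires per-event durations")
        values = events.durations
    elif use == "intervals":
        values = intervals(events, IntervalConvention.ONSET_TO_ONSET).values
    else:
        raise ValueError("use must be 'durations' or 'intervals'")
    model = detect_duration_categories(values, k_max=k_max, seed=seed)
    tm = transition_matrix(model.assignment, model.k)
    return model, tm
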