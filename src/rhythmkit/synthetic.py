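"""Synthetic pulse-train generators.

These produce the demonstration datasets used throughout the toolkit:

* an isochronous series (a pulse every ``period`` seconds, optionally
  jittered with Gaussian noise on the pulse positions);
* a random series (homogeneous Poisson process);
* a hierarchical series built from triplets of double pulses, giving
  exactly three interval scales;
* durational-category Markov chains (a probabilistic finite-state machine
  over interval categories);
* a speech-like lognormal interval generator calibrated so that half of
  the inter-event intervals fall between 0.19 and 0.25 s, emulating
  syllable-center annotations of read speech.

All generators quantize to a 1-ms grid by default (a 1-kHz sampling rate)
and are exactly reproducible given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .events import EventSeries

__all__ = [
    "IsochronousSpec",
    "PoissonSpec",
    "HierarchicalSpec",
    "DurationalMarkovSpec",
    "SpeechlikeSpec",
    "gen_isochronous",
    "gen_poisson",
    "gen_hierarchical",
    "gen_from_transitions",
    "gen_speechlike",
    "speechlike_log_sd",
]

_MAX_JITTER_RETRIES = 100


@dataclass(frozen=True)
class IsochronousSpec:
    period: float = 0.2
    duration: float = 10.0
    jitter_sd: float = 0.0
    seed: int = 0
    resolution: float = 0.001
    label: str = "isochronous"

    def __post_init__(self) -> None:
        if self.period <= 0 or self.duration < self.period:
            raise ValueError("need period > 0 and duration >= period")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.jitter_sd > 0 and self.period <= 2 * self.jitter_sd:
            warnings.warn("period <= 2*jitter_sd: jitter may reorder pulses", stacklevel=2)


@dataclass(frozen=True)
class PoissonSpec:
    rate: float = 12.0
    duration: float = 10.0
    seed: int = 0
    resolution: float = 0.001
    label: str = "random"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.rate * self.duration < 2:
            raise ValueError("expected event count rate*duration must be >= 2")


@dataclass(frozen=True)
class HierarchicalSpec:
    """Triplets of double pulses.

    One motif is six pulses: three pairs (pulses ``gap_within_pair`` apart),
    successive pairs ``gap_between_pairs`` apart (last pulse of one pair to
    first pulse of the next), and ``gap_between_triplets`` from the last
    pulse of a triplet to the first pulse of the next.  Jitter-free, the
    interval multiset is exactly {within, between-pairs, between-triplets}.
    """

    gap_within_pair: float = 0.05
    gap_between_pairs: float = 0.20
    gap_between_triplets: float = 0.60
    duration: float = 10.0
    jitter_sd: float = 0.0
    seed: int = 0
    resolution: float = 0.001
    label: str = "hierarchical"

    def __post_init__(self) -> None:
        if not (0 < self.gap_within_pair < self.gap_between_pairs < self.gap_between_triplets):
            raise ValueError(
                "gaps must satisfy 0 < within_pair < between_pairs < between_triplets"
            )


@dataclass(frozen=True)
class DurationalMarkovSpec:
    """Probabilistic finite-state machine over durational categories."""

    centroids: tuple = (0.4, 0.7, 1.3)
    category_sd: tuple = (0.04, 0.07, 0.13)
    transition: tuple = (
        (0.6, 0.3, 0.1),
        (0.2, 0.5, 0.3),
        (0.1, 0.3, 0.6),
    )
    initial: Optional[tuple] = None
    n_events: int = 1000
    seed: int = 0
    resolution: float = 0.001
    label: str = "markov"

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("centroids must be strictly increasing")
        p = np.asarray(self.transition, float)
        k = c.size
        if p.shape != (k, k):
            raise ValueError(f"transition must be {k}x{k}")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if len(self.category_sd) != k:
            raise ValueError("category_sd must have one entry per centroid")
        if self.initial is not None:
            pi = np.asarray(self.initial, float)
            if pi.shape != (k,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
                raise ValueError("initial must be a length-K probability vector")

    @property
    def k(self) -> int:
        return len(self.centroids)


def speechlike_log_sd(
    median: float = 0.218, q_low: float = 0.19, q_high: float = 0.25, mass: float = 0.5
) -> float:
    """log10-scale SD such that a lognormal with the given median places
    ``mass`` of its probability inside ``[q_low, q_high]``."""
    a = np.log10(q_low / median)
    b = np.log10(q_high / median)

    def deficit(sigma: float) -> float:
        return stats.norm.cdf(b / sigma) - stats.norm.cdf(a / sigma) - mass

    return float(optimize.brentq(deficit, 1e-4, 2.0))


@dataclass(frozen=True)
class SpeechlikeSpec:
    """Lognormal IEI generator emulating syllable-center timing of read
    speech: median IEI 0.218 s, log-scale spread calibrated so the
    interquartile range is approximately 0.19–0.25 s."""

    log_mu: float = float(np.log10(0.218))
    log_sd: float = field(default_factory=speechlike_log_sd)
    n_events: int = 300
    seed: int = 0
    resolution: float = 0.001
    label: str = "speech"

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        if self.n_events < 1:
            raise ValueError("n_events (number of intervals) must be >= 1")


def _dedupe_after_quantization(times: np.ndarray, resolution: float) -> np.ndarray:
    q = np.round(times / resolution) * resolution
    return np.unique(q)


def gen_isochronous(spec: IsochronousSpec) -> EventSeries:
    """Pulses at ``k*period`` plus independent Gaussian position jitter,
    quantized to ``resolution`` and clipped to ``[0, duration)``."""
    rng = np.random.default_rng(spec.seed)
    base = np.arange(0.0, spec.duration - 1e-12, spec.period)
    times = base.copy()
    if spec.jitter_sd > 0:
        times = base + rng.normal(0.0, spec.jitter_sd, base.size)
        for _ in range(_MAX_JITTER_RETRIES):
            bad = np.flatnonzero(np.diff(times) <= spec.resolution / 2)
            if bad.size == 0 and times[0] >= 0:
                break
            if times[0] < 0:
                times[0] = base[0] + abs(rng.normal(0.0, spec.jitter_sd))
            for i in bad:
                times[i + 1] = base[i + 1] + rng.normal(0.0, spec.jitter_sd)
        else:
            raise RuntimeError("could not jitter pulses without reordering")
    times = np.round(times / spec.resolution) * spec.resolution
    times = times[(times >= 0) & (times < spec.duration)]
    return EventSeries(
        times, 0.0, spec.duration, spec.resolution, label=spec.label
    )


def gen_poisson(spec: PoissonSpec) -> EventSeries:
    """Homogeneous Poisson sample on ``[0, duration)``.

    Events tied after 1-ms quantization are merged (dropped duplicates);
    the induced dead time is one resolution step and has negligible effect
    on counts or Allan-factor statistics at the rates used here.
    """
    seed = spec.seed
    for attempt in range(20):
        rng = np.random.default_rng(seed)
        n = rng.poisson(spec.rate * spec.duration)
        times = np.sort(rng.uniform(0.0, spec.duration, n))
        times = _dedupe_after_quantization(times, spec.resolution)
        times = times[times < spec.duration]
        if times.size >= 2:
            if attempt:
                warnings.warn(
                    f"poisson sample produced <2 events; reseeded {attempt}x", stacklevel=2
                )
            return EventSeries(times, 0.0, spec.duration, spec.resolution, label=spec.label)
        seed += 1
    raise RuntimeError("could not sample >= 2 Poisson events")


def _hierarchical_gaps(spec: HierarchicalSpec) -> np.ndarray:
    """Gap pattern of one motif (6 pulses): w, b, w, b, w, t."""
    w, b, t = spec.gap_within_pair, spec.gap_between_pairs, spec.gap_between_triplets
    return np.array([w, b, w, b, w, t])


def gen_hierarchical(spec: HierarchicalSpec) -> EventSeries:
    """Triplets of double pulses tiled to ``duration``; Gaussian jitter is
    applied to the gaps (preserving the three-scale structure), then times
    are quantized."""
    motif = _hierarchical_gaps(spec)
    motif_len = motif.sum()
    n_motifs = int(np.ceil(spec.duration / motif_len)) + 1
    gaps = np.tile(motif, n_motifs)[:-1]  # drop trailing inter-triplet gap
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for _ in range(_MAX_JITTER_RETRIES):
            jittered = gaps + rng.normal(0.0, spec.jitter_sd, gaps.size)
            if np.all(jittered > spec.resolution / 2):
                gaps = jittered
                break
        else:
            raise RuntimeError("could not jitter gaps while keeping them positive")
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = np.round(times / spec.resolution) * spec.resolution
    times = times[(times >= 0) & (times < spec.duration)]
    return EventSeries(times, 0.0, spec.duration, spec.resolution, label=spec.label)


def gen_from_transitions(spec: DurationalMarkovSpec) -> tuple[EventSeries, np.ndarray]:
    """Sample a durational-category Markov chain and realize it as a series.

    Returns the event series together with the ground-truth category label
    of each interval (length ``n_events``; the series has ``n_events + 1``
    events).  Interval ``i`` in category ``k`` is drawn from
    ``Normal(centroids[k], category_sd[k])`` truncated to be positive.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    centroids = np.asarray(spec.centroids, float)
    sds = np.asarray(spec.category_sd, float)
    p = np.asarray(spec.transition, float)
    pi = (
        np.asarray(spec.initial, float)
        if spec.initial is not None
        else np.full(k, 1.0 / k)
    )
    labels = np.empty(spec.n_events, dtype=int)
    labels[0] = rng.choice(k, p=pi)
    for i in range(1, spec.n_events):
        labels[i] = rng.choice(k, p=p[labels[i - 1]])
    gaps = rng.normal(centroids[labels], sds[labels])
    # truncate at zero: redraw any non-positive interval
    bad = gaps <= spec.resolution
    while bad.any():
        gaps[bad] = rng.normal(centroids[labels[bad]], sds[labels[bad]])
        bad = gaps <= spec.resolution
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = np.round(times / spec.resolution) * spec.resolution
    series = EventSeries(
        times, 0.0, float(times[-1]), spec.resolution, label=spec.label
    )
    return series, labels


def gen_speechlike(spec: SpeechlikeSpec) -> EventSeries:
    """i.i.d. lognormal intervals: ``log10(IEI) ~ Normal(log_mu, log_sd)``."""
    rng = np.random.default_rng(spec.seed)
    log_iei = rng.normal(spec.log_mu, spec.log_sd, spec.n_events)
    gaps = np.maximum(10.0 ** log_iei, spec.resolution)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = np.round(times / spec.resolution) * spec.resolution
    # extremely short gaps can tie on the 1-ms grid; nudge forward
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + spec.resolution
    return EventSeries(
        times, 0.0, float(times[-1]), spec.resolution, label=spec.label
    )
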