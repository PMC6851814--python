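"""Allan-factor analysis of event series.

The Allan factor A(T) measures temporal clustering of point events at
timescale T: the observation window is partitioned into adjacent,
non-overlapping windows of length T with counts N_i, and

    A(T) = E[(N_{i+1} - N_i)^2] / (2 E[N_i])

For a homogeneous Poisson process A(T) = 1 at every timescale; values
rising with T indicate nested clustering (smaller event clusters inside
larger ones).  An AF *function* evaluates A(T) over a geometric ladder of
timescales, and its shape on log-log axes — linear coefficient (degree of
hierarchical structure) and quadratic coefficient (amount and direction of
change) — summarizes the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventSeries

__all__ = ["AFFunction", "AFShape", "af_variance", "af_function", "af_shape"]

#: floor applied to A(T) = 0 before taking log10 in shape fitting
AF_LOG_FLOOR = 1e-6


@dataclass(frozen=True)
class AFFunction:
    """Allan-factor values over increasing timescales.

    ``window_counts[j]`` is the number of adjacent windows M_j used at
    ``timescales[j]`` (always >= 2 for retained scales); ``af_values`` may
    contain NaN where no events fell in the analysis range (undefined,
    never imputed).
    """

    timescales: np.ndarray
    af_values: np.ndarray
    window_counts: np.ndarray
    n_events: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "timescales", np.asarray(self.timescales, float))
        object.__setattr__(self, "af_values", np.asarray(self.af_values, float))
        object.__setattr__(self, "window_counts", np.asarray(self.window_counts, int))

    def __len__(self) -> int:
        return int(self.timescales.size)


@dataclass(frozen=True)
class AFShape:
    """Quadratic log-log summary of an AF function.

    ``slope`` is the linear coefficient of the OLS fit of log10 A(T) on
    log10 T (degree of hierarchical temporal structure); ``curvature`` the
    quadratic coefficient (amount and direction of change across scales);
    ``fit_residual`` the RMS residual of the fit.
    """

    slope: float
    curvature: float
    fit_residual: float


def af_variance(events: EventSeries, T: float) -> float:
    """Allan factor of ``events`` at a single timescale ``T`` (seconds).

    Windows are anchored at ``t_start``; the trailing partial window is
    discarded.  Returns NaN (undefined) when the mean count is zero.
    """
    if events.n_events < 2:
        raise ValueError("at least 2 events required")
    span = events.span
    if T <= 0 or T > span / 2 + 1e-12:
        raise ValueError(f"timescale T={T} outside (0, span/2={span / 2}]")
    m = int(np.floor(span / T + 1e-9))
    # assign events to windows by index, with a half-resolution guard so an
    # event quantized onto a window edge lands in the window it opens
    idx = np.floor((events.times - events.t_start) / T + events.resolution / (2 * T)).astype(int)
    idx = idx[(idx >= 0) & (idx < m)]
    counts = np.bincount(idx, minlength=m)
    mean_count = counts.mean()
    if mean_count == 0:
        return float("nan")
    diffs = np.diff(counts)
    return float(np.mean(diffs**2) / (2.0 * mean_count))


def af_function(
    events: EventSeries,
    t_min: float | None = None,
    t_max: float | None = None,
    scales_per_octave: int = 1,
) -> AFFunction:
    """Allan factor over a geometric (default dyadic) ladder of timescales.

    Defaults keep at least four windows at the coarsest scale:
    ``t_min = 4 * resolution`` and ``t_max = span / 4``.  Scales where
    fewer than two full windows fit are dropped.
    """
    span = events.span
    if t_min is None:
        t_min = 4 * events.resolution
    if t_max is None:
        t_max = span / 4
    if not (0 < t_min < t_max <= span / 2 + 1e-12):
        raise ValueError("need 0 < t_min < t_max <= span/2")
    if scales_per_octave < 1:
        raise ValueError("scales_per_octave must be >= 1")
    n_octaves = np.log2(t_max / t_min)
    n_scales = int(np.floor(n_octaves * scales_per_octave + 1e-9)) + 1
    ladder = t_min * 2.0 ** (np.arange(n_scales) / scales_per_octave)
    ts, af, wc = [], [], []
    for T in ladder:
        m = int(np.floor(span / T + 1e-9))
        if m < 2:
            continue
        ts.append(T)
        af.append(af_variance(events, T))
        wc.append(m)
    if not ts:
        raise ValueError("no usable timescales in the requested range")
    return AFFunction(
        np.array(ts), np.array(af), np.array(wc), events.n_events, label=events.label
    )


def af_shape(af: AFFunction) -> AFShape:
    """Quadratic OLS fit of log10 A(T) against log10 T.

    Zero A(T) values are floored at ``AF_LOG_FLOOR`` before the log;
    undefined (NaN) values are excluded.  At least three usable points are
    required.
    """
    mask = np.isfinite(af.af_values)
    if mask.sum() < 3:
        raise ValueError("need at least 3 finite AF values for a quadratic fit")
    x = np.log10(af.timescales[mask])
    y = np.log10(np.maximum(af.af_values[mask], AF_LOG_FLOOR))
    coeffs = np.polynomial.polynomial.polyfit(x, y, 2)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return AFShape(slope=float(coeffs[1]), curvature=float(coeffs[2]), fit_residual=rms)
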