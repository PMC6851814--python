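"""Amplitude-envelope extraction and peak-event detection.

The amplitude envelope quantifies the bursts and lulls in acoustic
energy of a recording; its local maxima ("peak events") form the event
series fed to Allan-factor and interval analyses.  Extraction is the
magnitude of the analytic signal, low-pass filtered with a zero-lag
(forward-backward) filter so event times are not shifted, then decimated
to a modest envelope rate.

A trivial click-train renderer is included so the whole chain
(synthetic series -> audio -> envelope -> events) can be tested against
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .events import EventSeries

__all__ = [
    "Waveform",
    "Envelope",
    "amplitude_envelope",
    "peak_events",
    "render_clicks",
]


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 2:  # mix multichannel down to mono
            samples = samples.mean(axis=1)
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class Envelope:
    """Non-negative amplitude envelope at a decimated rate."""

    values: np.ndarray
    rate: float
    smoothing_cutoff: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if np.any(values < 0):
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


def amplitude_envelope(
    w: Waveform, cutoff: float = 32.0, out_rate: float = 200.0
) -> Envelope:
    """Analytic-signal magnitude, low-passed at ``cutoff`` Hz (zero-lag
    Butterworth, order 4), resampled to ``out_rate`` Hz.

    Defaults (32-Hz cutoff, 200-Hz envelope rate) capture syllable-rate
    energy bursts while suppressing pitch-rate ripple.
    """
    if not (cutoff < out_rate / 2 < w.sample_rate / 2):
        raise ValueError("need cutoff < out_rate/2 < sample_rate/2")
    if not w.samples.any():
        warnings.warn("silent input: returning an all-zero envelope", stacklevel=2)
        n_out = int(round(w.samples.size * out_rate / w.sample_rate))
        return Envelope(np.zeros(n_out), out_rate, cutoff)
    env = np.abs(signal.hilbert(w.samples))
    sos = signal.butter(4, cutoff, btype="low", fs=w.sample_rate, output="sos")
    env = signal.sosfiltfilt(sos, env)
    g = np.gcd(int(round(out_rate)), int(round(w.sample_rate)))
    env = signal.resample_poly(env, int(round(out_rate)) // g, int(round(w.sample_rate)) // g)
    return Envelope(np.clip(env, 0.0, None), out_rate, cutoff)


def peak_events(
    e: Envelope,
    min_prominence: float = 0.10,
    min_separation: float = 0.020,
    label: str = "",
) -> EventSeries:
    """Convert envelope local maxima to an event series.

    ``min_prominence`` is a fraction of the envelope maximum (per-recording
    normalization); peaks closer than ``min_separation`` seconds are thinned
    greedily, keeping the higher peak.  An empty series is returned when no
    peak qualifies.
    """
    if e.values.size == 0:
        raise ValueError("empty envelope")
    vmax = e.values.max()
    if vmax == 0:
        return EventSeries(np.empty(0), 0.0, e.values.size / e.rate, 1.0 / e.rate, label=label)
    peaks, props = signal.find_peaks(e.values, prominence=min_prominence * vmax)
    # greedy thinning: highest peaks claim their exclusion zone first
    order = np.argsort(e.values[peaks])[::-1]
    kept: list[int] = []
    min_gap = min_separation * e.rate
    for idx in peaks[order]:
        if all(abs(idx - k) >= min_gap for k in kept):
            kept.append(idx)
    kept = np.sort(np.array(kept, dtype=int)) if kept else np.empty(0, dtype=int)
    times = kept / e.rate
    return EventSeries(
        times, 0.0, e.values.size / e.rate, 1.0 / e.rate, label=label
    )


def render_clicks(
    events: EventSeries,
    sample_rate: float = 8000.0,
    click_freq: float = 1000.0,
    click_dur: float = 0.005,
    amplitude: float = 1.0,
) -> Waveform:
    """Render an event series as a train of Hann-windowed tone bursts,
    each centered on its event time so the envelope peak marks the event."""
    n = int(np.ceil(events.span * sample_rate)) + 1
    out = np.zeros(n)
    n_click = max(int(round(click_dur * sample_rate)) | 1, 3)  # odd length
    t = (np.arange(n_click) - n_click // 2) / sample_rate
    click = amplitude * np.hanning(n_click) * np.cos(2 * np.pi * click_freq * t)
    for onset in events.times - events.t_start:
        c = int(round(onset * sample_rate))
        i0, i1 = max(c - n_click // 2, 0), min(c + n_click // 2 + 1, n)
        out[i0:i1] += click[i0 - (c - n_click // 2) : n_click - ((c + n_click // 2 + 1) - i1)]
    return Waveform(out, sample_rate)
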