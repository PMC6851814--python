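"""File I/O: onset CSV (read/write), Praat TextGrid (read), WAV (read).

The canonical on-disk event format is a CSV with header columns
``onset[,offset][,label]``, times in seconds with dot decimals.  TextGrid
support covers point tiers (point times become onsets) and interval tiers
(interval starts become onsets, lengths become durations) in both the
long ("full") and short text formats.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .envelope import Waveform
from .events import EventSeries

__all__ = ["read_events", "write_events", "read_wav"]


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM (16/24/32-bit) or float WAV file; multichannel audio is
    mixed down to mono and integer samples scaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(data, float(rate))


def write_events(events: EventSeries, path: str | Path) -> None:
    """Write an event series as onset CSV (offset column when durations
    are present, label column when the series is labeled)."""
    cols: dict[str, object] = {"onset": events.times}
    if events.durations is not None:
        cols["offset"] = events.times + events.durations
    if events.label:
        cols["label"] = [events.label] * events.n_events
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def _events_from_table(
    df: pd.DataFrame, resolution: float, label: str, source: str
) -> EventSeries:
    if "onset" not in df.columns:
        raise ValueError(f"{source}: CSV must have an 'onset' column")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(onsets < 0):
        raise ValueError(f"{source}: negative onset times")
    order = np.argsort(onsets, kind="stable")
    if not np.array_equal(order, np.arange(onsets.size)):
        warnings.warn(f"{source}: onsets were unsorted; sorting", stacklevel=3)
        df = df.iloc[order]
        onsets = onsets[order]
    durations = None
    if "offset" in df.columns and df["offset"].notna().all():
        offsets = df["offset"].to_numpy(dtype=float)
        if np.any(offsets <= onsets):
            raise ValueError(f"{source}: every offset must exceed its onset")
        durations = offsets - onsets
    return EventSeries(onsets, 0.0, None, resolution, label=label, durations=durations)


def read_events(
    path: str | Path,
    format: str | None = None,
    tier: str | None = None,
    resolution: float = 0.001,
    label: str | None = None,
) -> EventSeries:
    """Read an event series from CSV or Praat TextGrid.

    ``format`` is inferred from the suffix when omitted.  For TextGrids,
    ``tier`` selects the named tier (required when several exist); a
    missing tier raises an error listing the available tiers.
    """
    path = Path(path)
    if format is None:
        format = "textgrid" if path.suffix.lower() == ".textgrid" else "csv"
    label = label if label is not None else path.stem
    if format == "csv":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        return _events_from_table(df, resolution, label, str(path))
    if format == "textgrid":
        return _read_textgrid(path, tier, resolution, label)
    raise ValueError(f"unknown format: {format!r}")


# --- minimal Praat TextGrid text-format reader ------------------------------

_NUM = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")
_STR = re.compile(r'"((?:[^"]|"")*)"')


def _tokenize_textgrid(text: str):
    """Yield the numbers and quoted strings of a TextGrid file in order;
    this stream is identical for the long and short formats."""
    # drop bracketed indices ("item [1]:", "points [2]:") before scanning
    text = re.sub(r"\[\s*\d*\s*\]", "", text)
    for m in re.finditer(r'"(?:[^"]|"")*"|-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?', text):
        tok = m.group(0)
        if tok.startswith('"'):
            yield tok[1:-1].replace('""', '"')
        else:
            yield float(tok)


def _read_textgrid(
    path: Path, tier: str | None, resolution: float, label: str
) -> EventSeries:
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    toks = list(_tokenize_textgrid(text))
    # header: "ooTextFile", "TextGrid", xmin, xmax, [<exists flag>,] ntiers
    if len(toks) < 5 or toks[0] != "ooTextFile" or toks[1] != "TextGrid":
        raise ValueError(f"{path}: not a Praat TextGrid text file")
    i = 2
    xmin, xmax = toks[i], toks[i + 1]
    i += 2
    if isinstance(toks[i], float):
        n_tiers = int(toks[i])
        i += 1
    else:
        raise ValueError(f"{path}: malformed TextGrid header")
    tiers: dict[str, tuple[str, list]] = {}
    for _ in range(n_tiers):
        kind = toks[i]  # "IntervalTier" or "TextTier"
        name = toks[i + 1]
        i += 4  # kind, name, tier xmin, tier xmax
        count = int(toks[i])
        i += 1
        items = []
        if kind == "IntervalTier":
            for _ in range(count):
                items.append((toks[i], toks[i + 1], toks[i + 2]))  # start, end, mark
                i += 3
        elif kind == "TextTier":
            for _ in range(count):
                items.append((toks[i], toks[i + 1]))  # time, mark
                i += 2
        else:
            raise ValueError(f"{path}: unknown tier class {kind!r}")
        tiers[name] = (kind, items)
    if tier is None:
        if len(tiers) != 1:
            raise ValueError(
                f"{path}: specify a tier; available: {sorted(tiers)}"
            )
        tier = next(iter(tiers))
    if tier not in tiers:
        raise ValueError(f"{path}: no tier {tier!r}; available: {sorted(tiers)}")
    kind, items = tiers[tier]
    if kind == "TextTier":
        onsets = np.array([t for t, _ in items])
        durations = None
    else:
        filled = [(s, e) for s, e, mark in items if str(mark).strip()]
        if not filled:  # fall back to all intervals when none is labeled
            filled = [(s, e) for s, e, _ in items]
        onsets = np.array([s for s, _ in filled])
        durations = np.array([e - s for s, e in filled])
    order = np.argsort(onsets, kind="stable")
    onsets = onsets[order]
    if durations is not None:
        durations = durations[order]
    return EventSeries(
        onsets, 0.0, float(xmax), resolution, label=label, durations=durations
    )
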