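"""Track file I/O and configuration round-tripping.

Two text dialects are supported for trajectory files: ``csv`` (header
``track_id,t,x,y[,state]``, the default output) and ``xyt`` (whitespace
separated ``x y t track_id`` without header, the classic single-molecule
text layout).  Output formatting is deterministic — fixed column order and
6-significant-digit floats — so runs are diffable byte for byte.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .clutch import CameraConfig, PhotoConfig, SimConfig
from .motion import ClassThresholds
from .tracks import Track, TrackSet

__all__ = ["ParseError", "read_tracks", "write_tracks",
           "save_config", "load_config"]

_FMT = "{:.6g}"


class ParseError(ValueError):
    """A trajectory file could not be parsed; the message carries the
    1-based line number (and track id where known)."""


def write_tracks(ts: TrackSet, path: str | Path, dialect: str = "csv") -> Path:
    """Write a TrackSet as text; see module docstring for dialects."""
    path = Path(path)
    has_state = any(tr.states is not None for tr in ts)
    lines: list[str] = []
    if dialect == "csv":
        header = "track_id,t,x,y" + (",state" if has_state else "")
        lines.append(header)
        for tr in ts:
            for i in range(len(tr)):
                row = (f"{tr.id},{_FMT.format(tr.t[i])},"
                       f"{_FMT.format(tr.x[i])},{_FMT.format(tr.y[i])}")
                if has_state:
                    s = int(tr.states[i]) if tr.states is not None else -1
                    row += f",{s}"
                lines.append(row)
    elif dialect == "xyt":
        for tr in ts:
            for i in range(len(tr)):
                lines.append(f"{_FMT.format(tr.x[i])} {_FMT.format(tr.y[i])} "
                             f"{_FMT.format(tr.t[i])} {tr.id}")
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'xyt')")
    path.write_text("\n".join(lines) + "\n")
    return path


def _sniff_dialect(first_line: str) -> str:
    return "csv" if "track_id" in first_line else "xyt"


def read_tracks(path: str | Path, dialect: str | None = None) -> TrackSet:
    """Parse a trajectory text file into a TrackSet.

    Malformed lines raise :class:`ParseError` naming the 1-based line
    number; non-monotone time within a track names the track id as well.
    The frame interval is taken from the first multi-sample track.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise ParseError(f"{path}: empty file")
    if dialect is None:
        dialect = _sniff_dialect(text[0])

    data: dict[int, list[tuple[float, float, float, int]]] = {}
    start = 1 if dialect == "csv" else 0
    for ln, raw in enumerate(text[start:], start=start + 1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split(",") if dialect == "csv" else line.split()
        try:
            if dialect == "csv":
                tid = int(fields[0])
                t, x, y = (float(v) for v in fields[1:4])
                state = int(fields[4]) if len(fields) > 4 else -1
            else:
                x, y, t = (float(v) for v in fields[:3])
                tid = int(fields[3]) if len(fields) > 3 else 0
                state = int(fields[4]) if len(fields) > 4 else -1
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed line {ln}: {raw!r}") from exc
        data.setdefault(tid, []).append((t, x, y, state))

    tracks: list[Track] = []
    have_states = False
    for tid, rows in data.items():
        t = np.array([r[0] for r in rows])
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise ParseError(
                f"{path}: track {tid}: time not strictly increasing at "
                f"sample {bad + 1}")
        x = np.array([r[1] for r in rows])
        y = np.array([r[2] for r in rows])
        states = np.array([r[3] for r in rows])
        if np.all(states < 0):
            st = None
        else:
            st = states.astype(np.int8)
            have_states = True
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        tracks.append(Track(tid, t, x, y, dt, st))

    interval = next((tr.frame_interval for tr in tracks if len(tr) > 1), 1.0)
    for tr in tracks:
        tr.frame_interval = interval
    return TrackSet(tracks, interval, {"source": str(path)})


# -- configuration round trip --------------------------------------------

_SECTION_TYPES = {
    "sim": SimConfig,
    "photophysics": PhotoConfig,
    "camera": CameraConfig,
    "thresholds": ClassThresholds,
}


def save_config(sections: dict, path: str | Path) -> Path:
    """Serialize a dict of config dataclasses/plain values to YAML."""
    out = {}
    for key, val in sections.items():
        out[key] = dataclasses.asdict(val) if dataclasses.is_dataclass(val) \
            else val
    path = Path(path)
    path.write_text(yaml.safe_dump(out, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    """Inverse of :func:`save_config`: known sections come back as their
    dataclass types, everything else as plain values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, val in raw.items():
        cls = _SECTION_TYPES.get(key)
        if cls is not None and isinstance(val, dict):
            if "on_window" in val and isinstance(val["on_window"], list):
                val = dict(val, on_window=tuple(val["on_window"]))
            out[key] = cls(**val)
        else:
            out[key] = val
    return out
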