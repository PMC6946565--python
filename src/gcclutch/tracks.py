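"""Trajectory containers.

A :class:`Track` is the time-ordered 2D path of one molecule (or one growth
cone centroid, or one bead), sampled at a constant frame interval.  A
:class:`TrackSet` is a collection of tracks sharing that interval, the unit
the analysis pipeline operates on.  Coordinates are in micrometres, time in
seconds, package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Integer codes for the three kinetic states of a simulated actin molecule.
FREE, FLOW, BOUND = 0, 1, 2

STATE_NAMES = {FREE: "FREE", FLOW: "FLOW", BOUND: "BOUND"}


@dataclass
class Track:
    """Time-stamped 2D positions of a single molecule.

    Parameters
    ----------
    id : int
        Track identifier, unique within a :class:`TrackSet`.
    t, x, y : ndarray
        Sample times (s) and positions (µm).  ``t`` must be strictly
        increasing with constant spacing equal to ``frame_interval``.
    frame_interval : float
        Time between consecutive samples, in seconds.
    states : ndarray or None
        Optional per-sample kinetic state (``FREE``/``FLOW``/``BOUND``),
        carried by simulated tracks as ground truth.
    """

    id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.states is not None:
            self.states = np.asarray(self.states)
            if self.states.shape != self.t.shape:
                raise ValueError("states must align with samples")
        if len(self.t) > 1:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise ValueError(f"track {self.id}: time not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds (0 for 1 sample)."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def positions(self) -> np.ndarray:
        """(n, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])

    def slice(self, start: int, stop: int) -> "Track":
        """Contiguous sub-track by sample index (states sliced alongside)."""
        states = self.states[start:stop] if self.states is not None else None
        return Track(self.id, self.t[start:stop], self.x[start:stop],
                     self.y[start:stop], self.frame_interval, states)


@dataclass
class TrackSet:
    """A collection of tracks sharing one frame interval.

    ``metadata`` carries free-form provenance (simulation config, seed,
    processing history) and is propagated by the pipeline stages.
    """

    tracks: list[Track]
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tr in self.tracks:
            if not np.isclose(tr.frame_interval, self.frame_interval):
                raise ValueError(
                    f"track {tr.id} interval {tr.frame_interval} != "
                    f"set interval {self.frame_interval}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def lengths(self) -> np.ndarray:
        """Number of samples per track."""
        return np.array([len(tr) for tr in self.tracks], dtype=int)
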