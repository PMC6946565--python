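"""Optical-tweezers bead analysis: trap physics and escape statistics.

An adhesion-coated microsphere held in an optical trap on the growth-cone
surface is pulled rearward by the retrograde actin flow through
transmembrane receptors.  The trap is calibrated hydrodynamically: a known
fluid velocity V around the bead exerts the Stokes drag F = 6πRηV, and the
steady-state bead displacement δ gives the stiffness κ = F/δ.  The bead
escapes when its displacement reaches roughly the bead radius, so the
minimal escape force is F_esc = κ·R.  Bead recordings (2 min at 5 Hz) are
summarized by whether/when the bead escaped and by its post-escape
velocity, the initial slope of displacement vs time inside the 1–4 µm
peripheral band.

Unit convention: lengths µm, time s, viscosity Pa·s, forces pN.  With these
units the Stokes formula needs no numeric prefactor:
(1e-6 m/µm)² · (1e12 pN/N) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "stokes_drag", "calibrate_trap", "calibrate_trap_series", "escape_force",
    "TrapCalibration", "BeadTrack", "EscapeResult",
    "analyze_bead_track", "escape_probability", "mean_escape_time",
    "simulate_bead_track",
]

#: µm, Pa·s, µm/s → pN (exactly 1 in this unit system; kept explicit)
_STOKES_PN = 1.0


def stokes_drag(R: float, eta: float = 1e-3, V: float = 0.0) -> float:
    """Stokes drag F = 6πRηV on a sphere, in pN (R in µm, η in Pa·s,
    V in µm/s).  Linear in each argument; V = 0 gives 0."""
    if R <= 0 or eta <= 0 or V < 0:
        raise ValueError("R and eta must be > 0 and V >= 0")
    return _STOKES_PN * 6.0 * math.pi * R * eta * V


def calibrate_trap(F: float, delta: float) -> float:
    """Trap stiffness κ = F/δ (pN/µm) from one force/steady-displacement
    pair."""
    if delta <= 0:
        raise ValueError("steady-state displacement delta must be > 0")
    if F < 0:
        raise ValueError("force must be >= 0")
    return F / delta

def calibrate_trap_series(F: np.ndarray, delta: np.ndarray) -> float:
    """κ from several (F, δ) pairs by least squares through the origin
    (the trap is linear in the calibration range)."""
    F = np.asarray(F, dtype=float)
    d = np.asarray(delta, dtype=float)
    if np.any(d <= 0):
        raise ValueError("displacements must be > 0")
    return float(np.dot(d, F) / np.dot(d, d))


def escape_force(kappa: float, R: float) -> float:
    """Minimal escape force F_esc = κ·R (pN): the trap force at a bead
    displacement equal to the bead radius, beyond which the bead is lost."""
    if kappa < 0 or R < 0:
        raise ValueError("kappa and R must be >= 0")
    return kappa * R


@dataclass(frozen=True)
class TrapCalibration:
    """Full hydrodynamic trap calibration (all in µm/s/Pa·s/pN units)."""

    eta: float = 1e-3
    R: float = 0.5
    flow_V: float = 60.0
    delta: float = 0.12
    kappa: float = 4.7
    F_escape: float = 2.35

    @classmethod
    def from_flow(cls, flow_V: float, delta: float, R: float = 0.5,
                  eta: float = 1e-3) -> "TrapCalibration":
        F = stokes_drag(R, eta, flow_V)
        kappa = calibrate_trap(F, delta)
        return cls(eta=eta, R=R, flow_V=flow_V, delta=delta, kappa=kappa,
                   F_escape=escape_force(kappa, R))


@dataclass
class BeadTrack:
    """Bead displacement (µm, from the trap center) vs time (s)."""

    times: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.displacement < 0):
            raise ValueError("displacement is a distance, must be >= 0")

    @classmethod
    def from_xy(cls, times, x, y) -> "BeadTrack":
        """Displacement relative to the first (trap-center) position."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.hypot(x - x[0], y - y[0])
        return cls(np.asarray(times, dtype=float), d)

    @property
    def recording_length(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class EscapeResult:
    """Outcome of one bead recording."""

    escaped: bool
    escape_time: float = math.nan       # s; nan if never escaped
    post_escape_velocity: float = math.nan  # µm/s; nan if undefined
    velocity_ok: bool = False


def analyze_bead_track(track: BeadTrack, escape_radius: float = 0.5,
                       velocity_window: tuple[float, float] = (1.0, 4.0),
                       persistence: int = 2) -> EscapeResult:
    """Escape detection and post-escape velocity of one bead.

    The bead has escaped at the first crossing of ``escape_radius`` that
    persists for ``persistence`` consecutive samples (rejecting single-frame
    noise spikes).  The post-escape velocity is the ordinary-least-squares
    slope of displacement vs time restricted to the samples whose
    displacement lies in ``velocity_window`` (the 1–4 µm peripheral band)
    after the escape.
    """
    d, t = track.displacement, track.times
    above = d > escape_radius
    esc_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            esc_idx = i - persistence + 1
            break
    if esc_idx is None:
        return EscapeResult(escaped=False)
    esc_time = float(t[esc_idx])
    lo, hi = velocity_window
    sel = (t >= esc_time) & (d >= lo) & (d <= hi)
    if sel.sum() >= 2:
        slope = np.polyfit(t[sel], d[sel], 1)[0]
        return EscapeResult(True, esc_time, float(slope), velocity_ok=True)
    return EscapeResult(True, esc_time)


def escape_probability(results: list[EscapeResult], window: float = 60.0) -> float:
    """Fraction of beads that escaped within the first ``window`` seconds
    (over all recorded beads)."""
    if not results:
        raise ValueError("no bead results")
    n = sum(1 for r in results if r.escaped and r.escape_time <= window)
    return n / len(results)


def mean_escape_time(results: list[EscapeResult],
                     escaped_only: bool = True) -> float:
    """Average time to escape.  With ``escaped_only`` (the reporting
    convention used here), beads that never escaped are excluded rather
    than censored at the recording length."""
    times = [r.escape_time for r in results
             if r.escaped or not escaped_only]
    if not times:
        raise ValueError("no escaped beads" if escaped_only else "no beads")
    return float(np.mean(times))


def simulate_bead_track(kappa: float = 4.7, escape_time: float = 30.0,
                        flow_V: float = 0.12, noise: float = 0.0,
                        rng: np.random.Generator | None = None,
                        duration: float = 120.0, rate_hz: float = 5.0,
                        escape_radius: float = 0.5) -> BeadTrack:
    """Synthetic bead recording: bounded jitter in the trap until
    ``escape_time``, then linear drift at the retrograde flow speed.

    In the trap the displacement is |Gaussian| jitter clipped below the
    escape radius; after escape it is escape_radius + flow_V·(t − t_esc)
    plus jitter.  With ``noise = 0`` and ``escape_time > duration`` the
    displacement never reaches the escape radius.
    """
    if rng is None:
        rng = np.random.default_rng()
    t = np.arange(0.0, duration + 0.5 / rate_hz, 1.0 / rate_hz)
    d = np.empty_like(t)
    trapped = t < escape_time
    jitter = np.abs(rng.normal(0.0, noise, size=t.shape)) if noise > 0 \
        else np.zeros_like(t)
    d[trapped] = np.minimum(jitter[trapped], 0.8 * escape_radius)
    out = ~trapped
    d[out] = escape_radius + flow_V * (t[out] - escape_time) + jitter[out]
    return BeadTrack(t, np.maximum(d, 0.0))
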