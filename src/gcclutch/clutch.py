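"""Stochastic molecular-clutch simulator of actin dynamics in a virtual growth cone.

The growth cone is modelled as a flat 2D cone (apex at the origin, radius 12
µm, half-angle 45°), in line with the flat, fan-like shape of real growth
cones.  Individual actin molecules are stepped at Δt = 50 ms through three
kinetic states:

``FREE``
    cytosolic monomer, fast Brownian motion (D = 3 µm²/s).  Within an
    0.5 µm band under the leading edge it can polymerize onto a filament
    (rate ``k_poly``) and join the retrograde flow.
``FLOW``
    filamentous actin moving rearward at the retrograde flow speed ``V_flow``
    (radial coordinate decremented by V·Δt each step) with slow lateral
    diffusion D′ = 0.003 µm²/s.  Flowing filaments can transiently couple to
    substrate-immobilized adhesion complexes (N-cadherin) at rate ``k_c`` —
    the molecular clutch engaging — and depolymerize at rate ``k_d``.
    Filaments reaching the 4 µm basal region without depolymerizing are
    forced to disassemble.
``BOUND``
    clutch engaged: the molecule is nearly immobilized (D″ = 0.001 µm²/s)
    until it uncouples at rate ``k_u``.  The ratio k_c/k_u is the coupling
    strength of the clutch.

Free monomers never bind adhesions.  The simulator doubles as the synthetic
trajectory generator for the tracking pipeline: :func:`apply_photophysics`
emulates mEos2 stochastic activation/bleaching and :func:`downsample_to_camera`
emulates the 250 ms camera integration and 2 Hz frame selection that together
turn a 3200-step ground-truth path into the ~320-frame observed record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tracks import BOUND, FLOW, FREE, Track, TrackSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError", "SimConfig", "PhotoConfig", "CameraConfig",
    "ClutchSimulator", "simulate_molecule", "simulate_ensemble",
    "apply_photophysics", "apply_photophysics_set", "downsample_to_camera",
    "simulate_observed",
]


class ConfigError(ValueError):
    """A simulation parameter is outside its physical domain."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the virtual growth cone and the clutch kinetics.

    Lengths in µm, times in s, diffusivities in µm²/s, rates in 1/s.
    ``coupling_strength`` (k_c/k_u) is derived, not set.
    """

    cone_radius: float = 12.0       # leading edge at r = 12 µm
    cone_half_angle: float = 45.0   # degrees
    dt: float = 0.05
    duration: float = 160.0
    D_free: float = 3.0
    D_flow_lateral: float = 0.003   # D' — lateral noise of flowing filaments
    D_bound: float = 0.001          # D'' — residual motion of bound molecules
    V_flow: float = 0.10            # retrograde flow speed, 0.05–0.15 µm/s
    edge_band: float = 0.5          # polymerization zone below the leading edge
    k_poly: float = 0.5
    k_c: float = 0.2                # coupling (clutch engagement) rate
    k_u: float = 0.05               # uncoupling rate; varied 0.001–0.8
    k_d: float = 0.05               # spontaneous depolymerization rate
    base_band: float = 4.0          # basal region forcing disassembly
    n_molecules: int = 400
    seed: int = 0

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.duration / self.dt))

    @property
    def coupling_strength(self) -> float:
        return self.k_c / self.k_u

    def validate(self) -> None:
        for name in ("cone_radius", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("D_free", "D_flow_lateral", "D_bound", "V_flow",
                     "edge_band", "k_poly", "k_c", "k_u", "k_d", "base_band"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 < self.cone_half_angle <= 90:
            raise ConfigError(f"cone_half_angle must be in (0, 90], got {self.cone_half_angle}")
        if self.n_molecules < 0:
            raise ConfigError(f"n_molecules must be >= 0, got {self.n_molecules}")
        for name in ("k_poly", "k_c", "k_u", "k_d"):
            if self.dt * getattr(self, name) >= 1:
                raise ConfigError(
                    f"dt*{name} = {self.dt * getattr(self, name):.3g} >= 1: "
                    "per-step probability invalid; reduce dt or the rate")
        if self.edge_band >= self.cone_radius:
            raise ConfigError("edge_band must be < cone_radius")
        if self.base_band >= self.cone_radius:
            raise ConfigError("base_band must be < cone_radius")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhotoConfig:
    """mEos2 photophysics: random activation then exponential photobleaching.

    ``on_window`` is the interval (s) within which a molecule turns
    fluorescent, uniformly at random; it then bleaches after an exponential
    time of mean ``off_lifetime_mean``.  The 2.0 s default is calibrated so
    that, after camera down-sampling and the >7-frame filter, surviving
    trajectory lengths have a median near 9–11 frames, matching typical
    sptPALM recordings.
    """

    on_window: tuple[float, float] = (0.0, 150.0)
    off_lifetime_mean: float = 2.0
    seed: int = 0

    def validate(self, duration: float | None = None) -> None:
        lo, hi = self.on_window
        if not 0 <= lo <= hi:
            raise ConfigError(f"on_window must satisfy 0 <= lo <= hi, got {self.on_window}")
        if duration is not None and hi > duration:
            raise ConfigError(f"on_window {self.on_window} exceeds duration {duration}")
        if not self.off_lifetime_mean > 0:
            raise ConfigError("off_lifetime_mean must be > 0")


@dataclass(frozen=True)
class CameraConfig:
    """Camera integration: sum groups of ``sum_group`` frames, keep one of
    ``keep_every``.  Defaults reproduce the 250 ms exposure / 2 Hz protocol
    (5 × 50 ms summed, one image out of two kept)."""

    sum_group: int = 5
    keep_every: int = 2

    def validate(self) -> None:
        if self.sum_group < 1:
            raise ConfigError("sum_group must be >= 1")
        if self.keep_every < 1:
            raise ConfigError("keep_every must be >= 1")

    def exposure(self, dt: float) -> float:
        return self.sum_group * dt


class ClutchSimulator:
    """Monte-Carlo engine stepping molecules through the clutch state machine.

    One master seed spawns an independent substream per molecule (substream
    index = molecule id), so ensembles are bit-reproducible and individual
    molecules can be re-simulated in isolation.
    """

    def __init__(self, config: SimConfig):
        config.validate()
        self.config = config

    # -- single molecule ---------------------------------------------------

    def simulate_molecule(self, rng: np.random.Generator, molecule_id: int = 0,
                          r0: float | None = None, theta0: float | None = None,
                          initial_state: int = FREE) -> Track:
        """Simulate one molecule; see :func:`simulate_molecule`."""
        c = self.config
        n = c.n_steps
        half = math.radians(c.cone_half_angle)
        R = c.cone_radius
        s_free = math.sqrt(2.0 * c.D_free * c.dt)
        s_flow = math.sqrt(2.0 * c.D_flow_lateral * c.dt)
        s_bound = math.sqrt(2.0 * c.D_bound * c.dt)
        p_poly = c.k_poly * c.dt
        p_bind = c.k_c * c.dt
        p_unbind = c.k_u * c.dt
        p_depoly = c.k_d * c.dt
        vdt = c.V_flow * c.dt
        edge_r = R - c.edge_band

        # Fixed draw schedule: 2 draws for the initial position, then per
        # step 2 normals + 4 uniforms, consumed in a fixed order regardless
        # of state, so trajectories are reproducible from the substream alone.
        r_init = rng.uniform(0.0, R)
        th_init = rng.uniform(-half, half)
        if r0 is not None:
            r_init = float(r0)
        if theta0 is not None:
            th_init = math.radians(theta0)
        normals = rng.standard_normal((n, 2)).tolist()
        uniforms = rng.random((n, 4)).tolist()

        xs = [0.0] * n
        ys = [0.0] * n
        sts = [0] * n
        x = r_init * math.cos(th_init)
        y = r_init * math.sin(th_init)
        st = initial_state
        xs[0], ys[0], sts[0] = x, y, st

        for k in range(1, n):
            n1, n2 = normals[k]
            u_poly, u_bind, u_unbind, u_depoly = uniforms[k]
            r = math.hypot(x, y)

            # 1. polymerization test (FREE monomers in the edge band)
            if st == FREE and r >= edge_r and u_poly < p_poly:
                st = FLOW

            # 2. motion update
            if st == FREE:
                x += s_free * n1
                y += s_free * n2
                r = math.hypot(x, y)
                th = math.atan2(y, x)
                # reflect at the leading edge and the straight sides
                if r > R:
                    r = 2.0 * R - r
                if th > half:
                    th = 2.0 * half - th
                elif th < -half:
                    th = -2.0 * half - th
                if th > half:
                    th = half
                elif th < -half:
                    th = -half
                if r > R:
                    r = R
                elif r < 0.0:
                    r = 0.0
                x = r * math.cos(th)
                y = r * math.sin(th)
            elif st == FLOW:
                th = math.atan2(y, x)
                r = r - vdt
                if r < 0.0:
                    r = 0.0
                x = r * math.cos(th) + s_flow * n1
                y = r * math.sin(th) + s_flow * n2
                r = math.hypot(x, y)
                th = math.atan2(y, x)
                # lateral noise clamped to the cone (no reflection: the
                # rearward drift, not the noise, dominates this regime)
                if th > half:
                    th = half
                elif th < -half:
                    th = -half
                if r > R:
                    r = R
                x = r * math.cos(th)
                y = r * math.sin(th)
            else:  # BOUND
                x += s_bound * n1
                y += s_bound * n2
                r = math.hypot(x, y)
                th = math.atan2(y, x)
                if th > half:
                    th = half
                elif th < -half:
                    th = -half
                if r > R:
                    r = R
                x = r * math.cos(th)
                y = r * math.sin(th)

            # 3. coupling / uncoupling test
            if st == FLOW:
                if u_bind < p_bind:
                    st = BOUND
                # 4. depolymerization test, then forced disassembly at base
                elif u_depoly < p_depoly:
                    st = FREE
                elif r <= c.base_band:
                    st = FREE
            elif st == BOUND:
                if u_unbind < p_unbind:
                    st = FLOW

            xs[k], ys[k], sts[k] = x, y, st

        t = np.arange(n, dtype=float) * c.dt
        return Track(molecule_id, t, np.array(xs), np.array(ys), c.dt,
                     states=np.array(sts, dtype=np.int8))

    # -- ensemble ----------------------------------------------------------

    def simulate_ensemble(self) -> TrackSet:
        """Simulate ``n_molecules`` independent molecules (fixed-seed
        reproducible; per-molecule substreams spawned from the master seed)."""
        c = self.config
        seqs = np.random.SeedSequence(c.seed).spawn(c.n_molecules)
        tracks = [
            self.simulate_molecule(np.random.Generator(np.random.PCG64(s)), i)
            for i, s in enumerate(seqs)
        ]
        meta = {"config": c, "seed": c.seed}
        return TrackSet(tracks, frame_interval=c.dt, metadata=meta)


def simulate_molecule(config: SimConfig, rng: np.random.Generator,
                      **kw) -> Track:
    """Simulate one actin molecule in the virtual growth cone.

    Returns a track of exactly ``floor(duration/dt)`` samples with
    per-sample kinetic states.  Keyword arguments ``r0`` (µm), ``theta0``
    (degrees) and ``initial_state`` pin the starting condition for
    controlled experiments; by default the start is uniform over the cone's
    polar coordinates.
    """
    return ClutchSimulator(config).simulate_molecule(rng, **kw)


def simulate_ensemble(config: SimConfig) -> TrackSet:
    """Simulate the full ensemble (default 400 molecules) reproducibly."""
    return ClutchSimulator(config).simulate_ensemble()


def apply_photophysics(track: Track, photo: PhotoConfig,
                       rng: np.random.Generator) -> Track:
    """Restrict a ground-truth track to its fluorescent window.

    The molecule turns on at a uniform random time in ``photo.on_window``
    and bleaches after an exponential time of mean ``photo.off_lifetime_mean``;
    the returned sub-track may be empty if the window contains no sample.
    """
    if len(track) == 0:
        raise ValueError("track is empty")
    photo.validate()
    t_on = rng.uniform(*photo.on_window)
    t_off = (math.inf if math.isinf(photo.off_lifetime_mean)
             else rng.exponential(photo.off_lifetime_mean))
    start = int(np.searchsorted(track.t, t_on, side="left"))
    stop = int(np.searchsorted(track.t, t_on + t_off, side="right"))
    return track.slice(start, stop)


def apply_photophysics_set(ts: TrackSet, photo: PhotoConfig) -> TrackSet:
    """Apply photophysics to every track (per-track substreams of
    ``photo.seed``); tracks whose window is empty are dropped."""
    seqs = np.random.SeedSequence(photo.seed).spawn(len(ts))
    out = []
    for tr, s in zip(ts, seqs):
        sub = apply_photophysics(tr, photo, np.random.Generator(np.random.PCG64(s)))
        if len(sub):
            out.append(sub)
    meta = dict(ts.metadata, photophysics=photo)
    return TrackSet(out, ts.frame_interval, meta)


def downsample_to_camera(ts: TrackSet, cam: CameraConfig) -> TrackSet:
    """Emulate camera integration on ground-truth trajectories.

    Positions in each group of ``sum_group`` consecutive samples are averaged
    (the trajectory-level equivalent of summing the corresponding images),
    then one group out of ``keep_every`` is retained, so a 3200-frame path at
    50 ms becomes 320 frames at 0.5 s.  Tracks shorter than one group are
    dropped with a warning.  Per-sample states, when present, are carried
    over as the state of each kept group's central sample.
    """
    cam.validate()
    g, k = cam.sum_group, cam.keep_every
    new_dt = ts.frame_interval * g * k
    out = []
    n_dropped = 0
    for tr in ts:
        ngroups = len(tr) // g
        if ngroups == 0:
            n_dropped += 1
            continue
        m = ngroups * g
        tg = tr.t[:m].reshape(ngroups, g).mean(axis=1)
        xg = tr.x[:m].reshape(ngroups, g).mean(axis=1)
        yg = tr.y[:m].reshape(ngroups, g).mean(axis=1)
        sel = slice(k - 1, None, k)  # one group out of keep_every
        tg, xg, yg = tg[sel], xg[sel], yg[sel]
        if len(tg) == 0:
            n_dropped += 1
            continue
        states = None
        if tr.states is not None:
            centers = np.arange(ngroups) * g + g // 2
            states = tr.states[centers][sel]
        out.append(Track(tr.id, tg, xg, yg, new_dt, states))
    if n_dropped:
        logger.warning("downsample_to_camera: dropped %d track(s) shorter "
                       "than %d samples", n_dropped, g)
    meta = dict(ts.metadata, camera=cam)
    return TrackSet(out, new_dt, meta)


def select_by_state(ts: TrackSet, state: int, min_fraction: float = 0.8) -> TrackSet:
    """Keep tracks whose ground-truth states are at least ``min_fraction``
    in ``state`` (e.g. FLOW-dominated tracks).

    The trajectory-level counterpart of the image-blur elimination of fast
    monomers: the simulator knows each sample's kinetic state, so regime-pure
    subsets can be selected exactly.  Tracks without state labels are dropped.
    """
    kept = [tr for tr in ts
            if tr.states is not None
            and np.mean(tr.states == state) >= min_fraction]
    meta = dict(ts.metadata, state_filter=(state, min_fraction))
    return TrackSet(kept, ts.frame_interval, meta)


def simulate_observed(config: SimConfig,
                      photo: PhotoConfig | None = None,
                      cam: CameraConfig | None = None) -> TrackSet:
    """Full synthetic-observation chain: simulate ground truth, apply
    photophysics, down-sample to the camera protocol."""
    photo = photo if photo is not None else PhotoConfig(
        on_window=(0.0, min(150.0, config.duration)), seed=config.seed + 1)
    cam = cam if cam is not None else CameraConfig()
    ts = simulate_ensemble(config)
    ts = apply_photophysics_set(ts, photo)
    return downsample_to_camera(ts, cam)
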