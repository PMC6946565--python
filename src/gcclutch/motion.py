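"""Per-trajectory motion analysis: MSD, anomalous/directed fits, classification.

The central quantity is the time-averaged mean squared displacement of a
track,

    MSD(τ) = ⟨ |r(t+τ) − r(t)|² ⟩_t ,

fitted either by the anomalous power law MSD = 4D·t^α (the exponent α
separates confined, α < 0.5, Brownian, 0.5 ≤ α < 1.5, and directed, α ≥ 1.5,
motion) or, for directed trajectories, by MSD = 4D·t + V²·t² whose quadratic
term yields the transport velocity V.  Both fits follow the
model-object/results-object convention: build the model from an
:class:`MSDCurve`, call ``fit()``, read estimates off the returned results.

Also here: the mobility split on the initial-slope diffusion coefficient
(confined vs mobile at D = 0.015 µm²/s by default), track-length filtering,
growth-cone centroid kinematics (velocity and pause detection) and EB3 comet
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .tracks import Track, TrackSet

__all__ = [
    "MSDCurve", "compute_msd", "MotionFit", "ClassThresholds",
    "PowerLawMSDModel", "DirectedMSDModel",
    "fit_msd_power", "fit_msd_directed", "diffusion_from_initial_slope",
    "classify_alpha", "classify_mobility", "resolution_d_threshold",
    "filter_tracks", "classify_trackset", "class_fractions",
    "KinematicsResult", "growth_cone_kinematics",
    "EB3Metrics", "eb3_metrics",
]

CLASSES = ("confined", "brownian", "directed")


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track.  ``lags`` are positive multiples of
    the frame interval (MSD(0) = 0 by convention and is not stored);
    ``n_pairs`` counts the displacement pairs averaged at each lag."""

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return len(self.lags)

    def plot(self, fit: "MotionFit | None" = None, ax=None):
        """MSD vs lag, optionally overlaid with a fitted model curve."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags, self.values, "o", ms=4, label="MSD")
        if fit is not None:
            t = np.linspace(self.lags[0], self.lags[-1], 200)
            if fit.model == "power":
                ax.plot(t, 4 * fit.D * t ** fit.alpha,
                        label=f"$4Dt^\\alpha$ ($\\alpha$={fit.alpha:.2f})")
            elif fit.model == "directed":
                ax.plot(t, 4 * fit.D * t + (fit.V or 0.0) ** 2 * t ** 2,
                        label=f"$4Dt+V^2t^2$ (V={fit.V:.3g} µm/s)")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("MSD (µm²)")
        ax.legend()
        return ax


def compute_msd(track: Track, max_lag_fraction: float = 1.0) -> MSDCurve:
    """Time-averaged MSD over all ordered same-lag pairs of a track.

    Lags run from one frame interval up to ``max_lag_fraction`` of the
    track's (n − 1) available lags (at least one lag).
    """
    n = len(track)
    if n < 2:
        raise ValueError("MSD requires a track with at least 2 samples")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    p = track.positions()
    lags = np.arange(1, max_lag + 1)
    values = np.empty(max_lag)
    for m in lags:
        d = p[m:] - p[:-m]
        values[m - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    return MSDCurve(lags * track.frame_interval, values, n - lags)


@dataclass
class MotionFit:
    """Result of an MSD model fit.

    ``model`` is ``"power"`` (D, alpha from 4D·t^α), ``"directed"``
    (D, V from 4D·t + V²·t²) or ``"linear"`` (initial-slope D).
    ``degenerate`` flags fits on uninformative curves (all-zero MSD,
    negative quadratic term, negative initial slope).
    """

    D: float
    alpha: float | None = None
    V: float | None = None
    model: str = "power"
    fit_window: int = 0
    residual: float = 0.0
    degenerate: bool = False

    def summary(self) -> str:
        parts = [f"model={self.model}", f"D={self.D:.4g} um^2/s"]
        if self.alpha is not None:
            parts.append(f"alpha={self.alpha:.3f}")
        if self.V is not None:
            parts.append(f"V={self.V:.4g} um/s")
        parts.append(f"lags={self.fit_window}")
        if self.degenerate:
            parts.append("DEGENERATE")
        return "MotionFit(" + ", ".join(parts) + ")"


@dataclass(frozen=True)
class ClassThresholds:
    """Classification cut-offs.

    α boundaries: confined below 0.5, directed at and above 1.5 (boundary
    inclusive on the directed side, exclusive on the confined side).
    ``D_confined`` defaults to the N-cadherin value 0.015 µm²/s; use 0.022
    for Vangl2 (Methods value; the Results section of the source study also
    quotes 0.025 for the same cut — see docs).  Tracks with negative initial
    MSD slope are assigned the sentinel 1e-5 µm²/s, which always classifies
    as confined.
    """

    alpha_confined: float = 0.5
    alpha_directed: float = 1.5
    D_confined: float = 0.015
    D_sentinel: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 < self.alpha_confined < self.alpha_directed < 2:
            raise ValueError("need 0 < alpha_confined < alpha_directed < 2")
        if not self.D_confined > self.D_sentinel:
            raise ValueError("need D_confined > D_sentinel")


VANGL2_THRESHOLDS = ClassThresholds(D_confined=0.022)


class PowerLawMSDModel:
    """Anomalous-diffusion power law MSD = 4D·t^α, fitted by ordinary least
    squares in log–log space over the first ``fit_fraction`` of lags (never
    fewer than ``min_lags``).  α is clamped to [0, 2]."""

    def __init__(self, msd: MSDCurve, fit_fraction: float = 0.25,
                 min_lags: int = 4):
        self.msd = msd
        self.fit_fraction = fit_fraction
        self.min_lags = min_lags

    def fit(self) -> MotionFit:
        msd = self.msd
        nfit = max(self.min_lags, int(np.floor(self.fit_fraction * len(msd))))
        nfit = min(nfit, len(msd))
        t = msd.lags[:nfit]
        v = msd.values[:nfit]
        pos = v > 0
        if pos.sum() < 2:
            return MotionFit(D=0.0, alpha=0.0, model="power",
                             fit_window=nfit, degenerate=True)
        lt, lv = np.log(t[pos]), np.log(v[pos])
        slope, intercept = np.polyfit(lt, lv, 1)
        alpha = float(np.clip(slope, 0.0, 2.0))
        D = float(np.exp(intercept) / 4.0)
        resid = float(np.sum((lv - (slope * lt + intercept)) ** 2))
        return MotionFit(D=D, alpha=alpha, model="power",
                         fit_window=nfit, residual=resid)


class DirectedMSDModel:
    """Directed-motion model MSD = 4D·t + V²·t², fitted by nonnegative least
    squares so D ≥ 0 and V² ≥ 0 by construction (a fitted V² of zero is
    flagged degenerate)."""

    def __init__(self, msd: MSDCurve, fit_fraction: float = 1.0,
                 min_lags: int = 4):
        self.msd = msd
        self.fit_fraction = fit_fraction
        self.min_lags = min_lags

    def fit(self) -> MotionFit:
        msd = self.msd
        nfit = max(self.min_lags, int(np.floor(self.fit_fraction * len(msd))))
        nfit = min(nfit, len(msd))
        t = msd.lags[:nfit]
        v = msd.values[:nfit]
        A = np.column_stack([4.0 * t, t ** 2])
        coef, rnorm = nnls(A, v)
        D, v2 = float(coef[0]), float(coef[1])
        return MotionFit(D=D, V=float(np.sqrt(v2)), model="directed",
                         fit_window=nfit, residual=float(rnorm ** 2),
                         degenerate=(v2 == 0.0 and np.any(v > 0)))


def fit_msd_power(msd: MSDCurve, fit_fraction: float = 0.25,
                  min_lags: int = 4) -> MotionFit:
    """Fit MSD = 4D·t^α (log–log least squares); see :class:`PowerLawMSDModel`."""
    return PowerLawMSDModel(msd, fit_fraction, min_lags).fit()


def fit_msd_directed(msd: MSDCurve, fit_fraction: float = 1.0,
                     min_lags: int = 4) -> MotionFit:
    """Fit MSD = 4D·t + V²·t² (nonnegative least squares)."""
    return DirectedMSDModel(msd, fit_fraction, min_lags).fit()


def diffusion_from_initial_slope(msd: MSDCurve, n_points: int = 4,
                                 th: ClassThresholds = ClassThresholds()) -> float:
    """Diffusion coefficient from the initial MSD slope.

    Ordinary least-squares line through the first ``n_points`` lags; the
    slope divided by 4 is D.  A negative slope (confined molecule whose MSD
    bends down within the fit window) returns the sentinel ``th.D_sentinel``.
    """
    if len(msd) < n_points:
        raise ValueError(f"need at least {n_points} lags, have {len(msd)}")
    t = msd.lags[:n_points]
    v = msd.values[:n_points]
    slope = np.polyfit(t, v, 1)[0]
    if slope < 0:
        return th.D_sentinel
    return float(slope / 4.0)


def resolution_d_threshold(resolution_um: float, n_points: int = 4,
                           dt: float = 0.02) -> float:
    """Mobility cut-off implied by the image spatial resolution: the D of a
    molecule exploring ``resolution_um²`` during the ``n_points``-lag
    initial-slope window, res²/(4·n_points·dt)."""
    return resolution_um ** 2 / (4.0 * n_points * dt)


def classify_alpha(fit: MotionFit | float,
                   th: ClassThresholds = ClassThresholds()) -> str:
    """Motion class from the anomalous exponent: ``confined`` (α < 0.5),
    ``brownian`` (0.5 ≤ α < 1.5) or ``directed`` (α ≥ 1.5)."""
    alpha = fit.alpha if isinstance(fit, MotionFit) else float(fit)
    if alpha is None:
        raise ValueError("classification requires a power-law fit with alpha")
    if alpha >= th.alpha_directed:
        return "directed"
    if alpha < th.alpha_confined:
        return "confined"
    return "brownian"


def classify_mobility(D: float, th: ClassThresholds = ClassThresholds()) -> str:
    """Mobility class from the initial-slope D: ``confined`` iff
    D < ``th.D_confined`` (strict), else ``mobile``."""
    if D < 0:
        raise ValueError("D must be >= 0 (or the sentinel)")
    return "confined" if D < th.D_confined else "mobile"


def filter_tracks(ts: TrackSet, min_frames: int = 7) -> TrackSet:
    """Keep tracks strictly longer than ``min_frames`` samples (the
    >7-frame selection: 8 frames kept, 7 dropped).  Idempotent."""
    kept = [tr for tr in ts if len(tr) > min_frames]
    meta = dict(ts.metadata, min_frames=min_frames)
    return TrackSet(kept, ts.frame_interval, meta)


def classify_trackset(ts: TrackSet,
                      th: ClassThresholds = ClassThresholds(),
                      fit_fraction: float = 0.25,
                      min_lags: int = 4) -> pd.DataFrame:
    """Per-track motion table: power-law fit, α class, directed-fit V,
    initial-slope D and mobility class for every track in the set.

    Tracks too short for the fits (fewer than ``min_lags + 1`` samples) are
    skipped; run :func:`filter_tracks` first to make the selection explicit.
    """
    rows = []
    for tr in ts:
        if len(tr) < min_lags + 1:
            continue
        msd = compute_msd(tr)
        pw = fit_msd_power(msd, fit_fraction, min_lags)
        dr = fit_msd_directed(msd)
        D_slope = diffusion_from_initial_slope(msd, min(min_lags, len(msd)), th)
        rows.append({
            "track_id": tr.id,
            "n_frames": len(tr),
            "D": pw.D,
            "alpha": pw.alpha,
            "motion_class": classify_alpha(pw, th),
            "V_directed": dr.V,
            "D_initial": D_slope,
            "mobility": classify_mobility(D_slope, th),
            "degenerate": pw.degenerate,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "n_frames", "D", "alpha", "motion_class",
        "V_directed", "D_initial", "mobility", "degenerate"])


def class_fractions(table: pd.DataFrame) -> pd.Series:
    """Fraction of tracks in each α class (confined/brownian/directed);
    sums to 1 over a non-empty table."""
    counts = table["motion_class"].value_counts()
    total = counts.sum()
    return pd.Series({c: counts.get(c, 0) / total for c in CLASSES})


# -- growth-cone kinematics and EB3 comets -------------------------------


@dataclass
class KinematicsResult:
    """Growth-cone centroid kinematics over a recording.

    Velocities in µm/min; a pause is a maximal run of at least
    ``pause_min`` seconds during which the centroid stays within
    ``pause_eps`` of the run's first position.
    """

    mean_velocity: float
    pauses: list[tuple[float, float]] = field(default_factory=list)
    total_pause_time: float = 0.0
    velocity_excluding_pauses: float = 0.0

    @property
    def n_pauses(self) -> int:
        return len(self.pauses)


def growth_cone_kinematics(centroid: Track, pause_min: float = 60.0,
                           pause_eps: float = 0.5) -> KinematicsResult:
    """Global velocity and pause statistics of a growth-cone centroid track.

    ``mean_velocity`` is the total path length divided by the total
    acquisition time (converted to µm/min); ``velocity_excluding_pauses``
    uses only path and time outside detected pauses.
    """
    if len(centroid) < 2:
        raise ValueError("kinematics requires at least 2 centroid samples")
    if pause_eps <= 0:
        raise ValueError("pause_eps must be > 0")
    p = centroid.positions()
    t = centroid.t
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total_time = t[-1] - t[0]
    mean_velocity = steps.sum() / total_time * 60.0

    pauses: list[tuple[float, float]] = []
    in_pause = np.zeros(len(t) - 1, dtype=bool)  # per-step flag
    i = 0
    n = len(t)
    while i < n - 1:
        j = i
        while j + 1 < n and np.linalg.norm(p[j + 1] - p[i]) <= pause_eps:
            j += 1
        if j > i and (t[j] - t[i]) >= pause_min:
            pauses.append((float(t[i]), float(t[j] - t[i])))
            in_pause[i:j] = True
            i = j
        else:
            i += 1

    total_pause = float(sum(d for _, d in pauses))
    moving_time = total_time - total_pause
    moving_path = steps[~in_pause].sum()
    v_excl = moving_path / moving_time * 60.0 if moving_time > 0 else 0.0
    return KinematicsResult(float(mean_velocity), pauses, total_pause,
                            float(v_excl))


@dataclass
class EB3Metrics:
    """Microtubule plus-end (EB3 comet) transport velocity (µm/s) and
    particle lifetime (s)."""

    V: float
    lifetime: float


def eb3_metrics(track: Track, rate_hz: float = 2.0) -> EB3Metrics:
    """Comet velocity from the directed MSD fit; lifetime = number of time
    points divided by the acquisition rate (2 Hz by default)."""
    lifetime = len(track) / rate_hz
    if len(track) >= 5:
        fit = fit_msd_directed(compute_msd(track))
        v = fit.V or 0.0
    else:
        v = np.nan
    return EB3Metrics(float(v), float(lifetime))
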