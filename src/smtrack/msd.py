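"""Mean-squared-displacement analysis and diffusion-state decomposition.

All MSDs use the 2D convention ``MSD = 4 D t`` (tracks are 2D projections
of the nuclear volume).  Per-track apparent diffusion coefficients come
from a weighted linear fit of the first few lags with an offset term that
absorbs the localization-error floor (``b ~ 4 sigma_loc^2``).  Anomalous
exponents come from the log-log slope over an intermediate lag range, and
confined motion is characterized by the confinement radius R_c via

    MSD(t) = R_c^2 * (1 - exp(-4 D t / R_c^2)).

Populations of per-track D values are decomposed into 1-3 Gaussian
components on the log10(D) axis, with the component count selected by
BIC — the standard way to separate bound, intermediate, and freely
diffusing sub-populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

from .trackio import Track, TrackSet

__all__ = [
    "MSDCurve",
    "ConfinementFit",
    "DiffusionStates",
    "compute_msd",
    "fit_diffusion",
    "fit_alpha_and_rc",
    "population_rc",
    "sampling_volume",
    "fit_logD_mixture",
    "per_track_diffusion",
    "translocation_detect_time",
]

#: Apparent-D floor (µm²/s): below this a molecule is indistinguishable
#: from immobile at typical localization precision.
D_FLOOR = 1e-4

#: Dimensionality of the tracked coordinates; the MSD slope factor is 2*dim.
DIMENSIONS = 2


@dataclass
class MSDCurve:
    """MSD vs lag time, with the number of displacement pairs per lag."""

    lags: np.ndarray  # seconds, ascending
    msd: np.ndarray  # µm²
    counts: np.ndarray  # displacement pairs per lag
    source: str = "single_track"  # or "ensemble"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise ValueError("lags must be positive and ascending")
        if np.any(self.msd < 0) or np.any(self.counts < 1):
            raise ValueError("msd must be >= 0 and counts >= 1")


@dataclass(frozen=True)
class ConfinementFit:
    """Diffusion coefficient, confinement radius, and motion class."""

    D: float  # µm²/s
    R_c: float  # µm (inf when the fit is unbounded)
    alpha: float
    motion_class: str  # brownian / super_diffusive / sub_diffusive
    rc_unbounded: bool = False

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "R_c": self.R_c,
            "alpha": self.alpha,
            "motion_class": self.motion_class,
            "rc_unbounded": self.rc_unbounded,
        }


@dataclass
class DiffusionStates:
    """Gaussian-mixture decomposition of log10(D), slow to fast."""

    k: int
    weights: np.ndarray
    means: np.ndarray  # log10(D / µm² s⁻¹)
    sds: np.ndarray
    bic: float
    bic_by_k: dict

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "bic": self.bic,
            "bic_by_k": self.bic_by_k,
        }


def _track_msd(tr: Track, max_lag: int, frame_interval: float) -> MSDCurve | None:
    """Overlapping-window time-averaged MSD of one track."""
    n = len(tr)
    if n < 2:
        return None
    # index by frame number so gapped tracks pair only true lag-k frames
    fmin = int(tr.frames[0])
    span = int(tr.frames[-1]) - fmin + 1
    x = np.full(span, np.nan)
    y = np.full(span, np.nan)
    idx = tr.frames - fmin
    x[idx] = tr.x
    y[idx] = tr.y
    lags, msds, counts = [], [], []
    for lag in range(1, min(max_lag, span - 1) + 1):
        dx = x[lag:] - x[:-lag]
        dy = y[lag:] - y[:-lag]
        sq = dx * dx + dy * dy
        good = ~np.isnan(sq)
        m = int(good.sum())
        if m >= 1:
            lags.append(lag * frame_interval)
            msds.append(float(np.mean(sq[good])))
            counts.append(m)
    if not lags:
        return None
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts), "single_track")


def compute_msd(data: Track | TrackSet, max_lag: int = 20, frame_interval: float | None = None) -> MSDCurve:
    """Time-averaged MSD with overlapping windows.

    For a :class:`TrackSet` the per-track curves are combined into a
    count-weighted ensemble average; ``counts`` then totals displacement
    pairs over all tracks at each lag.
    """
    if max_lag < 1:
        raise ValueError(f"max_lag must be >= 1, got {max_lag}")
    if isinstance(data, Track):
        if frame_interval is None:
            dts = np.diff(data.t) / np.diff(data.frames)
            frame_interval = float(dts[0]) if len(dts) else 1.0
        out = _track_msd(data, max_lag, frame_interval)
        if out is None:
            raise ValueError("track too short for MSD (needs >= 2 localizations)")
        return out
    dt = frame_interval if frame_interval is not None else data.meta.frame_interval
    acc_msd = np.zeros(max_lag)
    acc_n = np.zeros(max_lag)
    for tr in data:
        c = _track_msd(tr, max_lag, dt)
        if c is None:
            continue
        k = np.rint(c.lags / dt).astype(int) - 1
        acc_msd[k] += c.msd * c.counts
        acc_n[k] += c.counts
    have = acc_n >= 1
    if not have.any():
        raise ValueError("no track long enough for MSD")
    lags = (np.nonzero(have)[0] + 1) * dt
    return MSDCurve(lags, acc_msd[have] / acc_n[have], acc_n[have], "ensemble")


def fit_diffusion(msd: MSDCurve, n_points: int = 4) -> tuple[float, float, bool]:
    """Apparent D from a weighted linear fit of the first ``n_points`` lags.

    Fits ``msd = 4 D tau + b`` (2D); the offset b absorbs the
    localization-error plateau (about ``4 sigma^2``).  Returns
    ``(D, b, flagged)``; a negative slope is floored at ``D_FLOOR`` µm²/s
    and flagged.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(msd.lags) < 2:
        raise ValueError("need >= 2 lags to fit a diffusion coefficient")
    m = min(n_points, len(msd.lags))
    t = msd.lags[:m]
    y = msd.msd[:m]
    w = np.sqrt(msd.counts[:m])
    slope, b = np.polyfit(t, y, 1, w=w)
    D = slope / (2 * DIMENSIONS)
    flagged = False
    if D < D_FLOOR:
        D = D_FLOOR
        flagged = True
    return float(D), float(b), flagged


def _confined_model(t, rc2, D):
    return rc2 * (1.0 - np.exp(-2 * DIMENSIONS * D * t / rc2))


def fit_alpha_and_rc(
    msd: MSDCurve,
    alpha_lag_range: tuple[int, int] = (2, 10),
    nucleus_radius: float | None = None,
) -> ConfinementFit:
    """Anomalous exponent and confinement radius of an MSD curve.

    ``alpha`` is the slope of log MSD vs log lag over ``alpha_lag_range``
    (1-based lag indices; the first lag is noise-dominated and the
    plateau flattens the tail, so an intermediate window is used).
    ``R_c`` and ``D`` come from a least-squares fit of the confined-
    diffusion model ``MSD(t) = R_c^2 (1 - exp(-4 D t / R_c^2))``.
    Motion is classed brownian for alpha in [0.9, 1.1], super-diffusive
    above, sub-diffusive below.  A non-convergent or runaway R_c fit is
    reported unbounded (R_c = inf, flag set).
    """
    if len(msd.lags) < 8:
        raise ValueError("need >= 8 lags for alpha / R_c fitting")
    i0 = max(0, alpha_lag_range[0] - 1)
    i1 = min(len(msd.lags), alpha_lag_range[1])
    if i1 - i0 < 2:
        i0, i1 = 0, len(msd.lags)
    pos = msd.msd[i0:i1] > 0
    alpha = float(
        np.polyfit(np.log(msd.lags[i0:i1][pos]), np.log(msd.msd[i0:i1][pos]), 1)[0]
    )
    if alpha > 1.1:
        motion = "super_diffusive"
    elif alpha < 0.9:
        motion = "sub_diffusive"
    else:
        motion = "brownian"

    plateau0 = float(msd.msd[-1])
    slope0 = msd.msd[0] / msd.lags[0]
    rc_unbounded = False
    try:
        popt, _ = curve_fit(
            _confined_model,
            msd.lags,
            msd.msd,
            p0=[max(plateau0, 1e-6), max(slope0 / (2 * DIMENSIONS), 1e-6)],
            sigma=1.0 / np.sqrt(msd.counts),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
        rc = math.sqrt(popt[0])
        D = float(popt[1])
        # plateau far beyond the sampled lags means confinement is not seen
        if popt[0] > 100.0 * msd.msd[-1] or (
            nucleus_radius is not None and rc >= nucleus_radius
        ):
            rc_unbounded = True
            rc = math.inf
    except (RuntimeError, ValueError):
        rc_unbounded = True
        rc = math.inf
        D = float(slope0 / (2 * DIMENSIONS))
    return ConfinementFit(D=D, R_c=rc, alpha=alpha, motion_class=motion, rc_unbounded=rc_unbounded)


def population_rc(fractions, rcs) -> float:
    """Population-weighted confinement radius: sum of f_i * R_c,i (µm).

    Reconciles sub-population confinement radii with a whole-population
    estimate, e.g. bound and free fractions at 50% each with R_c of
    0.13 and 0.5 µm give a total R_c of 0.315 µm.
    """
    f = np.asarray(fractions, dtype=float)
    r = np.asarray(rcs, dtype=float)
    if f.shape != r.shape or f.ndim != 1:
        raise ValueError("fractions and rcs must be 1D of equal length")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be >= 0 and sum to 1 (±1e-6)")
    return float(np.sum(f * r))


def sampling_volume(rc: float) -> float:
    """Spherical search volume (4/3)·π·R_c³ in µm³ for a confinement radius.

    R_c = 0.3 µm gives ~0.113 µm³; R_c = 1 µm (a diploid yeast nucleus)
    gives ~4.19 µm³.
    """
    if rc < 0:
        raise ValueError(f"rc must be >= 0, got {rc}")
    return (4.0 / 3.0) * math.pi * rc**3


def translocation_detect_time(speed_kbp_per_min: float, precision_nm: float, rise_per_bp_nm: float = 0.34) -> float:
    """Seconds for a processive enzyme's progress to exceed the
    localization precision, assuming a straight DNA template.

    A replisome at 1.6 kbp/min with 30 nm precision needs ~3.3 s; RNA
    Pol II elongating at 3.9 kbp/min needs ~1.4 s.
    """
    if speed_kbp_per_min <= 0 or precision_nm <= 0 or rise_per_bp_nm <= 0:
        raise ValueError("speed, precision and rise must all be > 0")
    nm_per_s = speed_kbp_per_min * 1000.0 / 60.0 * rise_per_bp_nm
    return precision_nm / nm_per_s


def per_track_diffusion(
    ts: TrackSet, n_points: int = 4, min_length: int = 5, max_lag: int | None = None
) -> np.ndarray:
    """Apparent D (µm²/s) per track, for mixture decomposition.

    Tracks shorter than ``min_length`` localizations are skipped; fits
    use ``n_points`` initial lags with an offset term (offset-on default).
    """
    out = []
    for tr in ts:
        if len(tr) < min_length:
            continue
        try:
            c = _track_msd(tr, max_lag or n_points + 1, ts.meta.frame_interval)
            if c is None or len(c.lags) < 2:
                continue
            D, _, _ = fit_diffusion(c, n_points)
            out.append(D)
        except ValueError:
            continue
    return np.array(out)


def fit_logD_mixture(
    d_values: np.ndarray,
    k_max: int = 3,
    seed: int = 0,
    n_init: int = 5,
    min_tracks_per_component: int = 10,
) -> DiffusionStates:
    """Decompose per-track D values into 1..k_max Gaussian states on log10 D.

    EM is initialized from quantile splits of the data (plus random
    restarts), the component count is selected by BIC, and components are
    reported slow to fast.  A component count k is eligible only with at
    least ``min_tracks_per_component * k`` tracks.
    """
    d = np.asarray(d_values, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    logd = np.log10(d).reshape(-1, 1)
    n = len(logd)
    best = None
    bic_by_k: dict[int, float] = {}
    for k in range(1, k_max + 1):
        if n < min_tracks_per_component * k:
            continue
        qs = np.quantile(logd, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            means_init=qs,
        ).fit(logd)
        bic = float(gm.bic(logd))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        raise ValueError(
            f"too few tracks ({n}) for any component count up to {k_max}"
        )
    bic, gm = best
    means = gm.means_.ravel()
    order = np.argsort(means)
    weights = gm.weights_[order]
    weights = weights / weights.sum()
    return DiffusionStates(
        k=gm.n_components,
        weights=weights,
        means=means[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        bic=bic,
        bic_by_k=bic_by_k,
    )
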