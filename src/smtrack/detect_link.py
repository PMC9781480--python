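"""Spot detection, sub-pixel localization, nearest-neighbour linking.

Detection follows the standard single-molecule recipe: a Gaussian
bandpass (difference of Gaussians) highlights diffraction-limited spots
above background, local maxima above a threshold become candidates, and
each candidate is refined by least-squares fitting of a symmetric 2D
Gaussian with constant offset inside a small window.

Linking is plain greedy nearest-neighbour between consecutive frames:
candidate pairs are sorted by distance (ties broken by detection index)
and assigned greedily, pairs farther apart than ``max_disp`` are not
linked, and unmatched detections start new tracks.  Gap closing is off
by default — bridging dark gaps inflates apparent dwell times and biases
the survival analysis downstream — but can be enabled via ``memory``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .trackio import AcquisitionMetadata, Localization, Track, TrackSet

__all__ = [
    "DetectionParams",
    "LinkParams",
    "detect_spots",
    "link_tracks",
    "render_kymograph",
    "noise_relative_threshold",
]


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection settings (pixel units unless noted).

    ``threshold`` is an absolute intensity level on the bandpassed image;
    use :func:`noise_relative_threshold` to derive one from image noise.
    """

    bandpass_low: float = 1.0
    bandpass_high: float = 4.0
    threshold: float = 1.0
    min_separation: int = 3
    fit_window: int = 7

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low < self.bandpass_high):
            raise ValueError("need 0 < bandpass_low < bandpass_high")
        if self.fit_window < 5 or self.fit_window % 2 == 0:
            raise ValueError("fit_window must be odd and >= 5")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


@dataclass(frozen=True)
class LinkParams:
    """Linking settings: ``max_disp`` in µm per frame interval; ``memory``
    is the number of frames a track may go undetected before termination."""

    max_disp: float = 0.5
    memory: int = 0

    def __post_init__(self) -> None:
        if not (self.max_disp > 0):
            raise ValueError("max_disp must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


def noise_relative_threshold(frame: np.ndarray, p: DetectionParams, k: float = 5.0) -> float:
    """Threshold at ``k`` robust standard deviations of the bandpassed frame.

    The robust sigma is the median absolute deviation scaled to Gaussian
    units, so bright spots do not inflate the estimate.
    """
    bp = _bandpass(np.asarray(frame, dtype=float), p)
    mad = np.median(np.abs(bp - np.median(bp)))
    return float(k * 1.4826 * mad)


def _bandpass(frame: np.ndarray, p: DetectionParams) -> np.ndarray:
    lo = ndimage.gaussian_filter(frame, p.bandpass_low)
    hi = ndimage.gaussian_filter(frame, p.bandpass_high)
    return lo - hi


def _gauss2d_residual(theta, yy, xx, z):
    amp, x0, y0, sig, off = theta
    model = off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sig**2))
    return (model - z).ravel()


def _fit_spot(frame: np.ndarray, row: int, col: int, half: int):
    """Refine one candidate by a symmetric-Gaussian fit; None on divergence."""
    ny, nx = frame.shape
    r0, r1 = max(0, row - half), min(ny, row + half + 1)
    c0, c1 = max(0, col - half), min(nx, col + half + 1)
    z = frame[r0:r1, c0:c1].astype(float)
    if z.size < 9:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1]
    off0 = float(z.min())
    amp0 = float(z.max() - off0)
    if amp0 <= 0:
        return None
    theta0 = [amp0, float(col), float(row), max(1.0, half / 3.0), off0]
    try:
        res = least_squares(
            _gauss2d_residual,
            theta0,
            args=(yy, xx, z),
            bounds=(
                [0, c0 - 1, r0 - 1, 0.3, -np.inf],
                [np.inf, c1, r1, 4.0 * half, np.inf],
            ),
            max_nfev=200,
        )
    except Exception:
        return None
    if not res.success:
        return None
    amp, x0, y0, sig, _ = res.x
    if not (c0 - 1 <= x0 <= c1 and r0 - 1 <= y0 <= r1) or amp <= 0:
        return None
    intensity = float(2.0 * np.pi * amp * sig * sig)  # integrated photons
    return float(x0), float(y0), intensity


def detect_spots(
    stack: np.ndarray,
    p: DetectionParams,
    meta: AcquisitionMetadata,
    diagnostics: dict | None = None,
) -> list[list[Localization]]:
    """Detect and localize spots in every frame of a single-channel stack.

    Returns one list of :class:`Localization` per frame, positions in µm.
    Candidates whose Gaussian fit diverges are discarded and tallied under
    ``diagnostics["fit_failures"]`` when a dict is supplied.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("expected a single-channel (T, Y, X) stack")
    half = p.fit_window // 2
    fails = 0
    out: list[list[Localization]] = []
    for f in range(stack.shape[0]):
        frame = stack[f]
        locs: list[Localization] = []
        if np.any(frame != frame.flat[0]):  # uniform frames carry no spots
            bp = _bandpass(frame, p)
            peaks = peak_local_max(
                bp,
                min_distance=p.min_separation,
                threshold_abs=p.threshold,
                exclude_border=False,
            )
            for row, col in peaks:
                fit = _fit_spot(frame, int(row), int(col), half)
                if fit is None:
                    fails += 1
                    continue
                x0, y0, intensity = fit
                # pixel i spans [i, i+1) pixel widths: its centre is i + 0.5
                locs.append(
                    Localization(
                        frame=f,
                        t=f * meta.frame_interval,
                        x=(x0 + 0.5) * meta.pixel_size,
                        y=(y0 + 0.5) * meta.pixel_size,
                        intensity=intensity,
                    )
                )
        out.append(locs)
    if diagnostics is not None:
        diagnostics["fit_failures"] = fails
    return out


def link_tracks(
    detections: list[list[Localization]],
    p: LinkParams,
    meta: AcquisitionMetadata,
) -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Deterministic: candidate pairs are sorted by (distance, track index,
    detection index) before greedy assignment.  A track unmatched for more
    than ``memory`` consecutive frames is terminated; with gap closing
    (``memory > 0``) the allowed displacement scales with the gap length.
    """
    active: list[dict] = []  # {"rows": [...], "last": Localization, "miss": int}
    done: list[list[Localization]] = []
    for frame_locs in detections:
        cands = []
        for ti, trk in enumerate(active):
            last = trk["last"]
            for di, loc in enumerate(frame_locs):
                dist = float(np.hypot(loc.x - last.x, loc.y - last.y))
                if dist <= p.max_disp * (trk["miss"] + 1):
                    cands.append((dist, ti, di))
        cands.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti]["rows"].append(frame_locs[di])
            active[ti]["last"] = frame_locs[di]
            active[ti]["miss"] = 0
        survivors = []
        for ti, trk in enumerate(active):
            if ti in used_t:
                survivors.append(trk)
            else:
                trk["miss"] += 1
                if trk["miss"] > p.memory:
                    done.append(trk["rows"])
                else:
                    survivors.append(trk)
        active = survivors
        for di, loc in enumerate(frame_locs):
            if di not in used_d:
                active.append({"rows": [loc], "last": loc, "miss": 0})
    done.extend(trk["rows"] for trk in active)
    done.sort(key=lambda rows: (rows[0].frame, rows[0].x, rows[0].y))
    tracks = []
    for tid, rows in enumerate(done):
        tracks.append(
            Track(
                tid,
                [r.frame for r in rows],
                [r.t for r in rows],
                [r.x for r in rows],
                [r.y for r in rows],
                [r.intensity for r in rows],
            )
        )
    return TrackSet(tracks=tracks, meta=meta)


def render_kymograph(stack: np.ndarray, axis: str = "y") -> np.ndarray:
    """Maximum-intensity projection kymograph.

    Projects each frame along the chosen spatial axis; the result has the
    retained axis as rows and time as columns, so an immobile bright
    molecule appears as a horizontal line.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    # frames are (T, Y, X); projecting along y keeps x, and vice versa
    proj = stack.max(axis=1 if axis == "y" else 2)  # (T, retained)
    return proj.T
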