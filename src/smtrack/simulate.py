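"""Ground-truth simulator for single-molecule tracking experiments.

Generates tracks (and optionally synthetic movies) with the statistical
structure the downstream analysis assumes:

* molecules switch between motion states (bound / diffusing) as a
  continuous-time Markov chain with exact exponential waiting times;
* displacements are Brownian, isotropic Gaussian with per-axis variance
  ``2 * D * dt``, reflected at a spherical confinement boundary;
* localization error is additive Gaussian noise per frame;
* photobleaching is Bernoulli per *exposure* (dark intervals in time-lapse
  imaging do not illuminate, so bleaching counts exposures, not seconds);
* the axial coordinate is simulated as 1D Brownian motion solely to drive
  defocalization loss — a molecule leaving the depth of field is lost.

Every run is driven by a single integer seed and is bit-reproducible.
Units are µm and seconds throughout; frames are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .trackio import AcquisitionMetadata, Track, TrackSet

__all__ = [
    "MotionState",
    "SimulationParams",
    "GroundTruth",
    "simulate_tracks",
    "simulate_movie",
]

BOUND_LABELS = ("bound_specific", "bound_nonspecific")
VALID_LABELS = BOUND_LABELS + ("diffusing",)


@dataclass(frozen=True)
class MotionState:
    """One motion state: a diffusion coefficient and optional confinement.

    Parameters
    ----------
    label : str
        One of ``bound_specific``, ``bound_nonspecific``, ``diffusing``.
    D : float
        Diffusion coefficient, µm²/s.  Bound states have D at or near 0.
    confinement_radius : float or None
        Radius of the sphere (µm) the molecule is confined to while in
        this state, centred on the position where the state was entered.
        ``None`` means only the nuclear boundary confines.
    """

    label: str
    D: float
    confinement_radius: float | None = None

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if not np.isfinite(self.D) or self.D < 0:
            raise ValueError(f"D must be finite and >= 0, got {self.D}")
        if self.confinement_radius is not None and not (self.confinement_radius > 0):
            raise ValueError("confinement_radius must be > 0 or None")

    @property
    def is_bound(self) -> bool:
        return self.label in BOUND_LABELS


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of one simulated SMT experiment.

    ``switch_rates[i][j]`` is the transition rate (1/s) from state i to
    state j; the diagonal is ignored.  ``frame_exposure`` and
    ``dark_interval`` define the time-lapse regime: wall-clock timestamps
    advance by their sum, but photobleaching is evaluated once per
    exposure only.
    """

    n_molecules: int
    states: tuple[MotionState, ...]
    switch_rates: tuple[tuple[float, ...], ...] = ()
    nucleus_radius: float = 1.0
    frame_exposure: float = 0.2
    dark_interval: float = 0.0
    n_frames: int = 100
    localization_sigma: float = 0.0
    bleach_prob_per_exposure: float = 0.0
    depth_of_field: float = math.inf
    seed: int = 0
    initial_state_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if len(self.states) < 1:
            raise ValueError("at least one MotionState is required")
        if not (self.nucleus_radius > 0):
            raise ValueError("nucleus_radius must be > 0")
        if not (self.frame_exposure > 0):
            raise ValueError("frame_exposure must be > 0")
        if self.dark_interval < 0:
            raise ValueError("dark_interval must be >= 0")
        if not (0.0 <= self.bleach_prob_per_exposure <= 1.0):
            raise ValueError("bleach_prob_per_exposure must be in [0, 1]")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if not (self.depth_of_field > 0):
            raise ValueError("depth_of_field must be > 0")
        object.__setattr__(self, "states", tuple(self.states))
        k = len(self.states)
        Q = np.zeros((k, k)) if not self.switch_rates else np.asarray(
            self.switch_rates, dtype=float
        )
        if Q.shape != (k, k):
            raise ValueError(f"switch_rates must be a {k}x{k} matrix")
        off = Q[~np.eye(k, dtype=bool)]
        if np.any(~np.isfinite(off)) or np.any(off < 0):
            raise ValueError("switch rates must be finite and >= 0")
        object.__setattr__(
            self, "switch_rates", tuple(tuple(row) for row in Q.tolist())
        )
        if self.initial_state_probs is not None:
            p = np.asarray(self.initial_state_probs, dtype=float)
            if p.shape != (k,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError("initial_state_probs must be a length-k simplex vector")

    @property
    def frame_interval(self) -> float:
        return self.frame_exposure + self.dark_interval

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q with rows summing to zero."""
        k = len(self.states)
        Q = np.asarray(self.switch_rates, dtype=float).reshape(k, k).copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the switching chain (uniform if absorbing)."""
        Q = self.rate_matrix
        k = Q.shape[0]
        if k == 1 or np.allclose(Q, 0):
            return np.full(k, 1.0 / k)
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        s = pi.sum()
        return pi / s if s > 0 else np.full(k, 1.0 / k)

    def metadata(self, label: str = "simulated") -> AcquisitionMetadata:
        return AcquisitionMetadata(
            pixel_size=0.11,
            exposure=self.frame_exposure,
            dark_interval=self.dark_interval,
            n_frames=self.n_frames,
            label=label,
        )


@dataclass
class GroundTruth:
    """The unobserved truth behind a simulated TrackSet.

    ``state_sequences[m]`` is the state index at each frame time for
    molecule m (length n_frames, independent of observation).
    ``dwell_times`` lists completed bound-state sojourns from the
    continuous-time realization as (molecule, state_index, dwell_s).
    ``bleach_frame[m]`` is the exposure index at which molecule m
    bleached, or -1 if it never did.
    """

    state_sequences: list[np.ndarray] = field(default_factory=list)
    dwell_times: list[tuple[int, int, float]] = field(default_factory=list)
    bleach_frame: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_D: tuple[float, ...] = ()
    state_fractions: tuple[float, ...] = ()

    def bound_dwells(self, states: Sequence[MotionState]) -> np.ndarray:
        """Completed dwell times (s) of all bound-state sojourns."""
        return np.array(
            [d for (_, si, d) in self.dwell_times if states[si].is_bound], dtype=float
        )


def _reflect_sphere(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Reflect a point into the sphere |pos - center| <= radius."""
    if not np.isfinite(radius):
        return pos
    v = pos - center
    d = float(np.linalg.norm(v))
    # Iterate: a single Brownian step can overshoot more than one radius.
    it = 0
    while d > radius and it < 8:
        pos = center + v * ((2.0 * radius - d) / d)
        v = pos - center
        d = abs(2.0 * radius - d)
        it += 1
    if d > radius:  # pathological overshoot: clamp to the boundary
        pos = center + v * (radius / d)
    return pos


def _sample_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if np.dot(p, p) <= radius * radius:
            return p


def _state_path(
    rng: np.random.Generator, Q: np.ndarray, s0: int, T: float
) -> list[tuple[float, int]]:
    """Exact CTMC realization: [(sojourn_duration, state), ...] covering [0, T]."""
    path = []
    t, s = 0.0, s0
    rates = -np.diag(Q)
    while t < T:
        r = rates[s]
        dt = math.inf if r <= 0 else rng.exponential(1.0 / r)
        dur = min(dt, T - t)
        path.append((dur, s))
        t += dur
        if dt < T - (t - dur):
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = np.clip(probs, 0, None)
            probs /= probs.sum()
            s = rng.choice(len(probs), p=probs)
    return path


def simulate_tracks(params: SimulationParams) -> tuple[TrackSet, GroundTruth]:
    """Simulate an SMT experiment; return observed tracks and the truth.

    Each molecule starts at frame 0 at a uniform position inside the
    nucleus, in a state drawn from the stationary distribution of the
    switching chain (override with ``initial_state_probs``).  The state
    path is realized with exact exponential waiting times; displacements
    within each frame interval integrate the piecewise-constant diffusion
    coefficient exactly, so dwell times carry no frame-rate bias.
    Observation ends at the first bleaching exposure (that exposure is
    still recorded) or at the first frame the molecule is out of focus.
    """
    rng = np.random.default_rng(params.seed)
    k = len(params.states)
    Q = params.rate_matrix
    dt_frame = params.frame_interval
    T = params.n_frames * dt_frame
    p0 = (
        np.asarray(params.initial_state_probs, dtype=float)
        if params.initial_state_probs is not None
        else params.stationary_distribution()
    )
    D = np.array([st.D for st in params.states])
    half_dof = params.depth_of_field / 2.0

    tracks: list[Track] = []
    truth = GroundTruth(
        true_D=tuple(D.tolist()),
        bleach_frame=np.full(params.n_molecules, -1, dtype=int),
    )
    time_in_state = np.zeros(k)

    for m in range(params.n_molecules):
        s0 = int(rng.choice(k, p=p0))
        path = _state_path(rng, Q, s0, T)
        for dur, s in path:
            time_in_state[s] += dur
        # completed sojourns only (the last is truncated by the movie end)
        for dur, s in path[:-1]:
            truth.dwell_times.append((m, s, dur))

        # truth state at each frame start, from the continuous realization
        edges = np.cumsum([dur for dur, _ in path])
        seg_states = np.array([s for _, s in path], dtype=np.int64)
        frame_times = np.arange(params.n_frames) * dt_frame
        seq = seg_states[np.minimum(np.searchsorted(edges, frame_times, side="right"),
                                    len(path) - 1)]
        truth.state_sequences.append(seq)

        # the bleaching exposure is decided up front: positions only need
        # propagating while the molecule can still be observed
        if params.bleach_prob_per_exposure > 0:
            n_bleach = int(rng.geometric(params.bleach_prob_per_exposure))
        else:
            n_bleach = params.n_frames + 1
        n_pos = min(params.n_frames, n_bleach)  # bleaching exposure is still seen

        pos = _sample_in_sphere(rng, params.nucleus_radius)
        conf_center = pos.copy()
        xs = np.empty(n_pos)
        ys = np.empty(n_pos)
        zs = np.empty(n_pos)
        seg_i, seg_left = 0, path[0][0]
        cur_state = int(path[0][1])
        eps = 1e-12 * dt_frame
        for f in range(n_pos):
            xs[f], ys[f], zs[f] = pos
            # propagate one frame interval, sub-stepping at state changes
            remaining = dt_frame
            while remaining > eps:
                last_seg = seg_i + 1 >= len(path)
                step = remaining if last_seg else min(remaining, seg_left)
                d_coef = D[cur_state]
                if d_coef > 0 and step > 0:
                    pos = pos + rng.normal(0.0, math.sqrt(2.0 * d_coef * step), size=3)
                    st = params.states[cur_state]
                    if st.confinement_radius is not None:
                        pos = _reflect_sphere(pos, conf_center, st.confinement_radius)
                    pos = _reflect_sphere(pos, np.zeros(3), params.nucleus_radius)
                remaining -= step
                seg_left -= step
                if seg_left <= eps and not last_seg:
                    seg_i += 1
                    seg_left, cur_state = path[seg_i][0], int(path[seg_i][1])
                    conf_center = pos.copy()

        # observation: defocalization loss, then the bleach cut-off
        n_obs = n_pos
        if np.isfinite(half_dof):
            out = np.nonzero(np.abs(zs) > half_dof)[0]
            if out.size:
                n_obs = int(out[0])
        if n_bleach <= params.n_frames and n_bleach <= n_obs:
            truth.bleach_frame[m] = n_bleach - 1
        if n_obs < 1:
            continue
        ox = xs[:n_obs].copy()
        oy = ys[:n_obs].copy()
        if params.localization_sigma > 0:
            ox += rng.normal(0.0, params.localization_sigma, n_obs)
            oy += rng.normal(0.0, params.localization_sigma, n_obs)
        frames = np.arange(n_obs, dtype=np.int64)
        tracks.append(
            Track(
                m,
                frames,
                frames * dt_frame,
                ox,
                oy,
                sigma=np.full(n_obs, params.localization_sigma),
            )
        )

    tot = time_in_state.sum()
    truth.state_fractions = tuple((time_in_state / tot).tolist()) if tot > 0 else ()
    return TrackSet(tracks=tracks, meta=params.metadata()), truth


def simulate_movie(
    tracks: TrackSet,
    psf_sigma: float,
    background: float,
    photons_per_molecule: float,
    shape: tuple[int, int] = (64, 64),
    origin: tuple[float, float] = (0.0, 0.0),
    shot_noise: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Render a TrackSet as a synthetic movie.

    Each frame is the sum of pixel-integrated 2D Gaussian spots at the
    track positions plus a uniform background, optionally with Poisson
    shot noise.  ``psf_sigma`` is in µm; pixel size comes from the track
    metadata; ``origin`` maps µm coordinates onto the pixel grid.

    Returns a float array of shape (n_frames, ny, nx); use
    :func:`smtrack.trackio.write_stack` for a 16-bit TIFF.
    """
    if not (psf_sigma > 0):
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma}")
    ny, nx = shape
    px = tracks.meta.pixel_size
    n_frames = tracks.meta.n_frames or (
        1 + max((int(tr.frames.max()) for tr in tracks), default=0)
    )
    movie = np.full((n_frames, ny, nx), float(background))
    # pixel-integrated Gaussian via the error function: exact photon count
    xe = np.arange(nx + 1) * px + origin[0]
    ye = np.arange(ny + 1) * px + origin[1]
    s = psf_sigma * math.sqrt(2.0)
    for tr in tracks:
        for i in range(len(tr)):
            f = int(tr.frames[i])
            if f >= n_frames:
                continue
            fx = 0.5 * (erf((xe - tr.x[i]) / s))
            fy = 0.5 * (erf((ye - tr.y[i]) / s))
            spot = photons_per_molecule * np.outer(np.diff(fy), np.diff(fx))
            movie[f] += spot
    if shot_noise:
        rng = np.random.default_rng(seed)
        movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    return movie
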