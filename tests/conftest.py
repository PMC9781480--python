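import numpy as np
import pytest

from smtrack import (
    AcquisitionMetadata,
    MotionState,
    SimulationParams,
    SurvivalCurve,
    Track,
    TrackSet,
    simulate_tracks,
)

FRAME_DT = 0.2


def curve_from_dwell_frames(dwell_frames, c_eq=0.46, frame_interval=FRAME_DT, n_min_frames=2):
    """Build a SurvivalCurve directly from dwell times in frame units.

    Mirrors build_survival's counting for pre-sampled dwells, so fitting
    behaviour can be studied without running the tracking pipeline.
    """
    kd = np.asarray(dwell_frames)
    kd = kd[kd >= n_min_frames]
    ks = np.arange(kd.min(), kd.max() + 1)
    counts = np.array([(kd >= k).sum() for k in ks], dtype=float)
    return SurvivalCurve(
        times=ks * frame_interval,
        S=c_eq * counts / counts[0],
        counts=counts,
        n0=len(kd),
        C_eq=c_eq,
        frame_interval=frame_interval,
    )


def stationary_track(track_id=0, n=10, x=1.0, y=2.0, dt=FRAME_DT):
    frames = np.arange(n)
    return Track(track_id, frames, frames * dt, np.full(n, x), np.full(n, y))


@pytest.fixture(scope="session")
def immobile_bleached_trackset():
    """10^4 immobile molecules bleaching at 0.05/exposure."""
    params = SimulationParams(
        n_molecules=10_000,
        states=(MotionState("bound_specific", 0.0),),
        n_frames=300,
        frame_exposure=FRAME_DT,
        bleach_prob_per_exposure=0.05,
        seed=11,
    )
    return simulate_tracks(params)


@pytest.fixture(scope="session")
def brownian_trackset():
    """Unconfined Brownian tracks, D = 1 µm²/s, noiseless."""
    params = SimulationParams(
        n_molecules=100,
        states=(MotionState("diffusing", 1.0),),
        n_frames=120,
        frame_exposure=0.01,
        nucleus_radius=50.0,
        seed=7,
    )
    return simulate_tracks(params)


@pytest.fixture
def meta():
    return AcquisitionMetadata(pixel_size=0.1, exposure=FRAME_DT, n_frames=20)
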