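"""Track tables, image stacks, and report I/O.

The canonical on-disk track format is a plain CSV with columns
``track_id, frame, t, x, y, intensity`` (and optional ``sigma``).
Coordinates are stored in micrometres, already scaled by the camera pixel
size, and frames are 0-based: analysis code never needs to know the camera
geometry.  Third-party tracker output (TrackMate, uTrack, ...) is imported
by exporting a table with these columns — a conversion recipe, not code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionMetadata",
    "Localization",
    "Track",
    "TrackSet",
    "TrackValidationError",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "read_stack",
    "write_stack",
    "write_report",
]

#: Columns every track table must provide.
MANDATORY_COLUMNS = ("track_id", "frame", "x", "y")
#: Columns written in this order; optional ones are filled with defaults.
ALL_COLUMNS = ("track_id", "frame", "t", "x", "y", "intensity", "sigma")


class TrackFormatError(ValueError):
    """A track table violates the on-disk format (e.g. a missing column)."""


class TrackValidationError(ValueError):
    """A track table parses but violates an invariant (e.g. duplicate frames)."""


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Timing and geometry of one acquisition.

    Parameters
    ----------
    pixel_size : float
        Camera pixel size in µm/pixel.
    exposure : float
        Illuminated exposure per frame, seconds.
    dark_interval : float
        Dark (non-illuminated) gap between consecutive exposures, seconds.
        Zero for continuous acquisition; positive for time-lapse imaging
        where long exposures are interspersed with dark periods.
    n_frames : int
        Number of frames in the movie.
    label : str
        Free-text description (protein, dye, condition).
    """

    pixel_size: float = 0.11
    exposure: float = 0.2
    dark_interval: float = 0.0
    n_frames: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.exposure > 0):
            raise ValueError(f"exposure must be > 0, got {self.exposure}")
        if self.dark_interval < 0:
            raise ValueError(f"dark_interval must be >= 0, got {self.dark_interval}")

    @property
    def frame_interval(self) -> float:
        """Wall-clock time between frame starts: exposure + dark_interval (s)."""
        return self.exposure + self.dark_interval

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Localization:
    """One sub-pixel localization of a molecule in one frame."""

    frame: int
    t: float
    x: float
    y: float
    intensity: float = np.nan
    sigma: float = np.nan

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")


class Track:
    """Ordered sub-pixel localizations of one molecule.

    Stores columns as numpy arrays for efficient analysis; iterate to get
    :class:`Localization` records.  Frames must be strictly increasing.
    """

    __slots__ = ("track_id", "frames", "t", "x", "y", "intensity", "sigma")

    def __init__(
        self,
        track_id: int,
        frames: Sequence[int],
        t: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        intensity: Sequence[float] | None = None,
        sigma: Sequence[float] | None = None,
    ) -> None:
        self.track_id = int(track_id)
        self.frames = np.asarray(frames, dtype=np.int64)
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n = len(self.frames)
        if n < 1:
            raise TrackValidationError(f"track {track_id}: needs >= 1 localization")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y)):
            if len(arr) != n:
                raise TrackValidationError(
                    f"track {track_id}: column {name} has length {len(arr)} != {n}"
                )
        self.intensity = (
            np.full(n, np.nan) if intensity is None else np.asarray(intensity, dtype=float)
        )
        self.sigma = np.full(n, np.nan) if sigma is None else np.asarray(sigma, dtype=float)
        d = np.diff(self.frames)
        if np.any(d == 0):
            raise TrackValidationError(f"track {track_id}: duplicate frame numbers")
        if np.any(d < 0):
            raise TrackValidationError(f"track {track_id}: frames not increasing")
        if np.any(np.diff(self.t) < 0):
            raise TrackValidationError(f"track {track_id}: time not nondecreasing")
        if np.any(self.frames < 0):
            raise TrackValidationError(f"track {track_id}: negative frame index")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Localization]:
        for i in range(len(self)):
            yield Localization(
                int(self.frames[i]),
                float(self.t[i]),
                float(self.x[i]),
                float(self.y[i]),
                float(self.intensity[i]),
                float(self.sigma[i]),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.track_id == other.track_id
            and np.array_equal(self.frames, other.frames)
            and np.allclose(self.t, other.t, equal_nan=True)
            and np.allclose(self.x, other.x, equal_nan=True)
            and np.allclose(self.y, other.y, equal_nan=True)
            and np.allclose(self.intensity, other.intensity, equal_nan=True)
        )


@dataclass
class TrackSet:
    """A collection of tracks plus the acquisition metadata they share."""

    tracks: list[Track] = field(default_factory=list)
    meta: AcquisitionMetadata = field(default_factory=AcquisitionMetadata)

    def __post_init__(self) -> None:
        ids = [tr.track_id for tr in self.tracks]
        if len(ids) != len(set(ids)):
            raise TrackValidationError("track_ids are not unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def n_localizations(self) -> int:
        return sum(len(tr) for tr in self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to a tidy table sorted by (track_id, frame)."""
        if not self.tracks:
            return pd.DataFrame({c: [] for c in ALL_COLUMNS})
        parts = []
        for tr in sorted(self.tracks, key=lambda tr: tr.track_id):
            parts.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "frame": tr.frames,
                        "t": tr.t,
                        "x": tr.x,
                        "y": tr.y,
                        "intensity": tr.intensity,
                        "sigma": tr.sigma,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: AcquisitionMetadata) -> "TrackSet":
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        df = df.copy()
        if "t" not in df.columns or df["t"].isna().all():
            df["t"] = df["frame"].astype(float) * meta.frame_interval
        if "intensity" not in df.columns:
            df["intensity"] = np.nan
        if "sigma" not in df.columns:
            df["sigma"] = np.nan
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            if g["frame"].duplicated().any():
                raise TrackValidationError(f"track {tid}: duplicate (track_id, frame) rows")
            tracks.append(
                Track(
                    int(tid),
                    g["frame"].to_numpy(dtype=np.int64),
                    g["t"].to_numpy(dtype=float),
                    g["x"].to_numpy(dtype=float),
                    g["y"].to_numpy(dtype=float),
                    g["intensity"].to_numpy(dtype=float),
                    g["sigma"].to_numpy(dtype=float),
                )
            )
        return cls(tracks=tracks, meta=meta)


def read_tracks(path: str | Path, meta: AcquisitionMetadata) -> TrackSet:
    """Read a CSV track table into a validated :class:`TrackSet`.

    The table must have header columns ``track_id, frame, x, y``; ``t``,
    ``intensity`` and ``sigma`` are optional.  If ``t`` is absent it is
    reconstructed as ``frame * (exposure + dark_interval)``.

    Raises
    ------
    TrackFormatError
        If a mandatory column is missing (the message names it).
    TrackValidationError
        If frames within a track are duplicated or non-monotone (the
        message names the track_id).
    """
    df = pd.read_csv(path)
    return TrackSet.from_dataframe(df, meta)


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    """Write a TrackSet as CSV with deterministic row/column order.

    Rows are sorted by (track_id, frame); numbers carry 6 significant
    digits, which round-trips localization coordinates at the nanometre
    level for micrometre-scale fields of view.
    """
    df = ts.to_dataframe()
    df = df.sort_values(["track_id", "frame"]) if len(df) else df
    with open(path, "w") as fh:
        fh.write(",".join(ALL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            vals = [
                str(int(row.track_id)),
                str(int(row.frame)),
                _fmt(row.t),
                _fmt(row.x),
                _fmt(row.y),
                _fmt(row.intensity),
                _fmt(row.sigma),
            ]
            fh.write(",".join(vals) + "\n")


def _fmt(v: float) -> str:
    if v != v:  # NaN
        return ""
    return f"{v:.6g}"


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into a (n_frames, ny, nx) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write an image stack as 16-bit multi-page TIFF (values clipped)."""
    out = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, out)


def write_report(obj: dict, path: str | Path) -> None:
    """Serialize an analysis report to JSON (numpy types coerced)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify, sort_keys=True)
        fh.write("\n")


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    raise TypeError(f"not JSON serializable: {type(v)}")
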