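"""Reading, writing and validating cell-track tables.

A *track* is the time-ordered sequence of one cell's 3D positions across
movie frames, in physical micrometres and seconds.  Two table dialects are
supported:

``long_csv``
    One row per (track, frame) with columns
    ``track_id, frame, t_s, x_um, y_um, z_um`` and optional metadata columns
    ``mouse, fov, group``.  This is the canonical schema; exports from
    tracking software are mapped onto it by renaming columns upstream.

``per_track_summary``
    One row per track with pre-computed statistics
    (``track_id, mean_velocity_um_min, displacement_um, track_length_um``),
    the shape of a typical tracking-software summary export.  Read back as
    a plain DataFrame since positions are not recoverable from it.

Coordinates are physical micrometres, never pixels: any pixel-to-µm
calibration belongs to whoever produced the table.  2D tables (no ``z_um``
column) are accepted and z is set to 0.  Missing frames within a track are
preserved as gaps — nothing is interpolated at this layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

LONG_CSV_REQUIRED = ["track_id", "frame", "t_s", "x_um", "y_um"]
LONG_CSV_OPTIONAL = ["z_um", "mouse", "fov", "group"]
SUMMARY_REQUIRED = [
    "track_id",
    "mean_velocity_um_min",
    "displacement_um",
    "track_length_um",
]
METADATA_COLUMNS = ["mouse", "fov", "group"]


@dataclass(frozen=True)
class TrackPoint:
    """One localisation: frame index, time (s) and position (µm)."""

    frame: int
    t: float
    x: float
    y: float
    z: float = 0.0

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track:
    """A cell's ordered positions plus free-form metadata (mouse, fov, group)."""

    track_id: str
    points: list[TrackPoint]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError(
                f"track {self.track_id!r}: needs >= 2 points, got {len(self.points)}"
            )
        frames = [p.frame for p in self.points]
        times = [p.t for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError(
                f"track {self.track_id!r}: frame indices must strictly increase"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"track {self.track_id!r}: timestamps must strictly increase"
            )
        for p in self.points:
            if not all(math.isfinite(v) for v in (p.t, p.x, p.y, p.z)):
                raise ValidationError(
                    f"track {self.track_id!r}: non-finite coordinate at frame {p.frame}"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in µm."""
        return np.array([[p.x, p.y, p.z] for p in self.points], dtype=float)

    def times(self) -> np.ndarray:
        """Timestamps in seconds."""
        return np.array([p.t for p in self.points], dtype=float)

    def frame_gaps(self) -> list[tuple[int, int]]:
        """Pairs of consecutive recorded frames with missing frames between them."""
        frames = [p.frame for p in self.points]
        return [(a, b) for a, b in zip(frames, frames[1:]) if b - a > 1]


@dataclass(frozen=True)
class ImagingGeometry:
    """Acquisition geometry of one intravital recording.

    Defaults follow a typical skin multiphoton protocol: frames every 60 s
    for 30 min, 2 µm z steps to ~100 µm depth.
    """

    field_x: float = 300.0
    field_y: float = 300.0
    depth: float = 100.0
    frame_interval: float = 60.0
    z_step: float = 2.0

    def __post_init__(self) -> None:
        for name in ("field_x", "field_y", "depth", "frame_interval", "z_step"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ImagingGeometry.{name} must be positive")
        if not (1.0 <= self.depth <= 1000.0):
            raise ValidationError(
                f"ImagingGeometry.depth {self.depth} outside sanity range [1, 1000] µm"
            )

    @property
    def n_frames_30min(self) -> int:
        """Frames in a 30-minute recording, endpoints included."""
        return int(round(30 * 60 / self.frame_interval)) + 1

    def volume_um3(self) -> float:
        return self.field_x * self.field_y * self.depth


def _require_columns(df: pd.DataFrame, required: Sequence[str], dialect: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{dialect}: missing required column(s) {', '.join(missing)}"
        )


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    """Build validated Tracks from a long-format DataFrame.

    Rows are grouped by ``track_id`` and sorted by ``frame`` within each
    group; metadata columns present in the table are attached to each track.
    Duplicated (track_id, frame) pairs raise :class:`ValidationError`.
    """
    _require_columns(df, LONG_CSV_REQUIRED, "long_csv")
    if "z_um" not in df.columns:
        logger.info("no z_um column: treating input as 2D, z set to 0")
        df = df.assign(z_um=0.0)
    tracks: list[Track] = []
    for track_id, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        if g["frame"].duplicated().any():
            dup = int(g.loc[g["frame"].duplicated(), "frame"].iloc[0])
            raise ValidationError(
                f"track {track_id!r}: duplicated frame index {dup}"
            )
        points = [
            TrackPoint(
                frame=int(r.frame), t=float(r.t_s),
                x=float(r.x_um), y=float(r.y_um), z=float(r.z_um),
            )
            for r in g.itertuples()
        ]
        metadata = {}
        for col in METADATA_COLUMNS:
            if col in g.columns:
                vals = g[col].dropna().unique()
                if len(vals) > 1:
                    raise ValidationError(
                        f"track {track_id!r}: inconsistent {col!r} metadata {list(vals)}"
                    )
                if len(vals) == 1:
                    metadata[col] = vals[0]
        tracks.append(Track(track_id=str(track_id), points=points, metadata=metadata))
    return tracks


def tracks_to_dataframe(tracks: Iterable[Track]) -> pd.DataFrame:
    """Long-format DataFrame for a collection of tracks (inverse of grouping)."""
    rows = []
    for tr in tracks:
        for p in tr.points:
            row = {
                "track_id": tr.track_id,
                "frame": p.frame,
                "t_s": p.t,
                "x_um": p.x,
                "y_um": p.y,
                "z_um": p.z,
            }
            for col in METADATA_COLUMNS:
                row[col] = tr.metadata.get(col, "")
            rows.append(row)
    columns = ["track_id", "frame", "t_s", "x_um", "y_um", "z_um", *METADATA_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def read_tracks(path: str | Path, dialect: str = "long_csv") -> list[Track] | pd.DataFrame:
    """Read a track table.

    Parameters
    ----------
    path
        CSV file location.
    dialect
        ``"long_csv"`` (returns a list of :class:`Track`) or
        ``"per_track_summary"`` (returns the summary DataFrame as-is after
        column validation; positions cannot be reconstructed from it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("empty track file: %s", path)
        return [] if dialect == "long_csv" else df
    if dialect == "long_csv":
        return tracks_from_dataframe(df)
    if dialect == "per_track_summary":
        _require_columns(df, SUMMARY_REQUIRED, "per_track_summary")
        return df
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tracks(
    tracks: Sequence[Track] | pd.DataFrame,
    path: str | Path,
    dialect: str = "long_csv",
) -> None:
    """Write tracks (or a summary table) to CSV.

    ``long_csv`` output round-trips through :func:`read_tracks` with
    coordinates preserved to 6 decimal places and metadata intact.  Tracks
    without a z coordinate are written with z = 0.
    """
    path = Path(path)
    if dialect == "long_csv":
        df = tracks_to_dataframe(tracks)
        df.to_csv(path, index=False, float_format="%.6f")
    elif dialect == "per_track_summary":
        if not isinstance(tracks, pd.DataFrame):
            raise TypeError("per_track_summary dialect expects a DataFrame")
        _require_columns(tracks, SUMMARY_REQUIRED, "per_track_summary")
        tracks.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
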