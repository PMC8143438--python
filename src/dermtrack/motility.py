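"""Per-track motility statistics.

For each track the standard intravital-imaging statistics are computed:

* **path length** — sum of Euclidean 3D step lengths between consecutive
  recorded points (µm).  Frame gaps are bridged by the single straight
  segment between the flanking points, which slightly underestimates the
  true path but fabricates no positions.
* **displacement** — straight-line distance from the first to the last
  point (µm).
* **mean velocity** — path length divided by total duration (µm/min).
  This is the gap-robust track-statistic definition; it coincides with the
  mean of per-step speeds only under uniform frame intervals.
* **confinement ratio** — displacement / path length, in [0, 1]:
  1 for perfectly straight migration, near 0 for a cell that returns to its
  origin.  A cell that never moves (path length 0) is assigned confinement
  0 by convention: the ratio is formally 0/0, and the convention is
  inconsequential downstream because such a cell has zero velocity and is
  classified static regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError
from .track_io import Track

#: Default per-track inclusion filters.  Tracks shorter than this are
#: dominated by localisation noise; both values are freely overridable
#: (set to 0 to disable).
DEFAULT_MIN_POINTS = 5
DEFAULT_MIN_DURATION_MIN = 5.0


@dataclass(frozen=True)
class TrackMetrics:
    """Motility statistics for one track."""

    track_id: str
    duration: float          # minutes
    path_length: float       # µm
    displacement: float      # µm
    mean_velocity: float     # µm/min
    confinement: float       # dimensionless, [0, 1]
    n_points: int
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Rejection:
    """Why a track was excluded from the metrics table."""

    track_id: str
    reason: str


def track_metrics(
    track: Track,
    min_duration: float = DEFAULT_MIN_DURATION_MIN,
    min_points: int = DEFAULT_MIN_POINTS,
) -> TrackMetrics | Rejection:
    """Compute motility statistics for one track, or reject it.

    Parameters
    ----------
    track
        A validated :class:`~dermtrack.track_io.Track`.
    min_duration
        Minimum track duration in minutes; shorter tracks are rejected.
    min_points
        Minimum number of recorded points.

    Returns
    -------
    TrackMetrics or Rejection
        A :class:`Rejection` carries the exclusion reason; callers decide
        whether to log or raise.
    """
    pos = track.positions()
    t = track.times()
    duration_min = (t[-1] - t[0]) / 60.0
    if track.n_points < min_points:
        return Rejection(track.track_id, f"n_points {track.n_points} < {min_points}")
    if duration_min < min_duration:
        return Rejection(
            track.track_id, f"duration {duration_min:.2f} min < {min_duration} min"
        )
    if duration_min == 0:
        raise ComputationError(
            f"track {track.track_id!r}: zero duration with {track.n_points} points"
        )
    steps = np.diff(pos, axis=0)
    path_length = float(np.linalg.norm(steps, axis=1).sum())
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    mean_velocity = path_length / duration_min
    confinement = displacement / path_length if path_length > 0 else 0.0
    # guard against tiny negative or >1 from float rounding
    confinement = min(max(confinement, 0.0), 1.0)
    return TrackMetrics(
        track_id=track.track_id,
        duration=duration_min,
        path_length=path_length,
        displacement=displacement,
        mean_velocity=mean_velocity,
        confinement=confinement,
        n_points=track.n_points,
        metadata=dict(track.metadata),
    )


def metrics_table(
    tracks: Iterable[Track],
    min_duration: float = DEFAULT_MIN_DURATION_MIN,
    min_points: int = DEFAULT_MIN_POINTS,
) -> tuple[list[TrackMetrics], list[Rejection]]:
    """Order-preserving :func:`track_metrics` over a collection.

    Returns the accepted metrics and a rejection log listing every excluded
    track with its reason.
    """
    accepted: list[TrackMetrics] = []
    rejected: list[Rejection] = []
    for tr in tracks:
        result = track_metrics(tr, min_duration=min_duration, min_points=min_points)
        if isinstance(result, Rejection):
            rejected.append(result)
        else:
            accepted.append(result)
    return accepted, rejected


def metrics_to_dataframe(metrics: Sequence[TrackMetrics]) -> pd.DataFrame:
    """Tidy per-track table (one row per cell) with metadata columns."""
    rows = []
    for m in metrics:
        row = {
            "track_id": m.track_id,
            "duration_min": m.duration,
            "path_length_um": m.path_length,
            "displacement_um": m.displacement,
            "mean_velocity_um_min": m.mean_velocity,
            "confinement": m.confinement,
            "n_points": m.n_points,
        }
        row.update(m.metadata)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_export(metrics: Sequence[TrackMetrics]) -> pd.DataFrame:
    """Per-track summary in the tracking-software export dialect."""
    return pd.DataFrame(
        {
            "track_id": [m.track_id for m in metrics],
            "mean_velocity_um_min": [m.mean_velocity for m in metrics],
            "displacement_um": [m.displacement for m in metrics],
            "track_length_um": [m.path_length for m in metrics],
        }
    )
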