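"""Behavioural classification of tracks on the velocity–confinement plane.

Plotting each cell's mean velocity against its confinement ratio and
cutting the plane at a velocity threshold of 2 µm/min and a confinement
threshold of 0.2 yields four behavioural quadrants:

* **Q1** — static: low velocity, low confinement.
* **Q2** — intermittent migration: average velocity stays below the motility
  threshold, but the confinement ratio is high.
* **Q3** — continuous (directed) migration: high velocity and high
  confinement ratio.
* **Q4** — fast but confined: high velocity with low confinement, cells
  that move quickly yet stay near their origin.

A cell is *motile* when its mean velocity is at or above the threshold
(velocity ≥ 2 µm/min moves a cell more than one cell width from its origin
over a 30-min recording), so the motile fraction equals %Q3 + %Q4.  The
boundary value itself counts as "high" on both axes; only the velocity
inclusivity is conventional in the field, and the confinement rule is
chosen to match it.

Note a deliberate semantic quirk carried over from how these quadrants are
used in the intravital literature: Q2 ("intermittent migration") pairs low
velocity with a HIGH confinement ratio, even though the confinement ratio
measures straightness.  The classification is applied exactly as defined;
no reinterpretation is attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .motility import TrackMetrics

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class Thresholds:
    """Quadrant cut-points on the velocity–confinement plane."""

    velocity_threshold: float = 2.0     # µm/min
    confinement_threshold: float = 0.2  # dimensionless

    def __post_init__(self) -> None:
        if self.velocity_threshold <= 0 or self.confinement_threshold <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass(frozen=True)
class BehaviourSummary:
    """Quadrant composition of one aggregation unit (fov, mouse or group)."""

    unit: str
    level: str                      # "fov" | "mouse" | "group"
    quadrant_pct: dict             # {"Q1": %, ..., "Q4": %}, sums to 100
    motile_fraction: float          # % = Q3 + Q4
    median_velocity: float          # µm/min
    n_tracks: int
    quadrant_sem: dict | None = None  # across sub-units, group level only
    n_units: int | None = None


def classify(metrics: TrackMetrics, thresholds: Thresholds = Thresholds()) -> str:
    """Assign one quadrant label; threshold values count as 'high'."""
    fast = metrics.mean_velocity >= thresholds.velocity_threshold
    straight = metrics.confinement >= thresholds.confinement_threshold
    if fast:
        return "Q3" if straight else "Q4"
    return "Q2" if straight else "Q1"


def motile_fraction(
    metrics: Sequence[TrackMetrics], thresholds: Thresholds = Thresholds()
) -> float:
    """Percentage of cells with mean velocity at or above the threshold."""
    if len(metrics) == 0:
        raise ComputationError("motile_fraction undefined for empty collection")
    n_motile = sum(
        1 for m in metrics if m.mean_velocity >= thresholds.velocity_threshold
    )
    return 100.0 * n_motile / len(metrics)


def velocity_distribution(
    metrics: Sequence[TrackMetrics], bin_width: float = 0.5
) -> tuple[pd.DataFrame, float]:
    """Relative-frequency histogram of mean velocities, plus the median.

    Bins are half-open ``[k*w, (k+1)*w)`` starting at zero; relative
    frequencies sum to 1.  Returns ``(histogram, median_velocity)`` where
    the histogram has columns ``bin_left, bin_right, rel_freq``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(metrics) == 0:
        raise ComputationError("velocity_distribution undefined for empty input")
    v = np.array([m.mean_velocity for m in metrics], dtype=float)
    idx = np.floor(v / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "rel_freq": counts / len(v),
        }
    )
    return hist, float(np.median(v))


def quadrant_percentages(
    metrics: Sequence[TrackMetrics], thresholds: Thresholds = Thresholds()
) -> dict:
    """Quadrant percentages for one set of tracks; values sum to 100."""
    if len(metrics) == 0:
        raise ComputationError("quadrant percentages undefined for empty input")
    labels = [classify(m, thresholds) for m in metrics]
    n = len(labels)
    return {q: 100.0 * labels.count(q) / n for q in QUADRANTS}


def _sem(values: np.ndarray) -> float:
    """Sample SD / sqrt(n); 0 for a single unit."""
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def _require_metadata(metrics: Sequence[TrackMetrics], keys: Sequence[str]) -> None:
    for m in metrics:
        for k in keys:
            if k not in m.metadata or m.metadata[k] in ("", None):
                raise ValidationError(
                    f"track {m.track_id!r}: missing {k!r} metadata required "
                    "for this aggregation level"
                )


def summarize_behaviour(
    metrics: Sequence[TrackMetrics],
    thresholds: Thresholds = Thresholds(),
    level: str = "mouse",
) -> list[BehaviourSummary]:
    """Hierarchical quadrant summaries.

    The aggregation hierarchy is fixed: quadrant percentages are computed
    within each field of view, fov values are averaged per mouse, and mouse
    values are averaged (mean ± SEM) per group — never pooled across the
    hierarchy.  SEM is the sample SD over sub-units divided by √(number of
    sub-units).

    Parameters
    ----------
    level
        ``"fov"``, ``"mouse"`` or ``"group"``; metadata down to that level
        must be present on every track.
    """
    if level not in ("fov", "mouse", "group"):
        raise ValueError(f"unknown aggregation level {level!r}")
    needed = {"fov": ["mouse", "fov"], "mouse": ["mouse"], "group": ["group", "mouse"]}
    _require_metadata(metrics, needed[level])

    # per-fov percentages are the base of every level
    _require_metadata(metrics, ["mouse", "fov"])
    by_fov: dict[tuple, list[TrackMetrics]] = {}
    for m in metrics:
        key = (m.metadata.get("group", ""), m.metadata["mouse"], m.metadata["fov"])
        by_fov.setdefault(key, []).append(m)
    fov_rows = []
    for (group, mouse, fov), ms in by_fov.items():
        pct = quadrant_percentages(ms, thresholds)
        fov_rows.append(
            {
                "group": group, "mouse": mouse, "fov": fov,
                **pct,
                "n_tracks": len(ms),
                "median_velocity": float(np.median([m.mean_velocity for m in ms])),
            }
        )
    fov_df = pd.DataFrame(fov_rows)

    def make_summary(unit: str, lvl: str, sub: pd.DataFrame,
                     sem: dict | None = None, n_units: int | None = None
                     ) -> BehaviourSummary:
        pct = {q: float(sub[q].mean()) for q in QUADRANTS}
        return BehaviourSummary(
            unit=unit,
            level=lvl,
            quadrant_pct=pct,
            motile_fraction=pct["Q3"] + pct["Q4"],
            median_velocity=float(sub["median_velocity"].mean()),
            n_tracks=int(sub["n_tracks"].sum()),
            quadrant_sem=sem,
            n_units=n_units,
        )

    if level == "fov":
        return [
            make_summary(f"{r.mouse}/{r.fov}", "fov", fov_df.loc[[i]])
            for i, r in fov_df.iterrows()
        ]

    mouse_df = (
        fov_df.groupby(["group", "mouse"], sort=True)
        .agg({**{q: "mean" for q in QUADRANTS},
              "n_tracks": "sum", "median_velocity": "mean"})
        .reset_index()
    )
    if level == "mouse":
        out = []
        for (group, mouse), sub in fov_df.groupby(["group", "mouse"], sort=True):
            out.append(make_summary(str(mouse), "mouse", sub))
        return out

    out = []
    for group, sub in mouse_df.groupby("group", sort=True):
        sem = {q: _sem(sub[q].to_numpy()) for q in QUADRANTS}
        out.append(make_summary(str(group), "group", sub, sem=sem,
                                n_units=len(sub)))
    return out


def summaries_to_dataframe(summaries: Iterable[BehaviourSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"unit": s.unit, "level": s.level}
        row.update({f"{q}_pct": s.quadrant_pct[q] for q in QUADRANTS})
        if s.quadrant_sem is not None:
            row.update({f"{q}_sem": s.quadrant_sem[q] for q in QUADRANTS})
        row.update(
            {
                "motile_fraction_pct": s.motile_fraction,
                "median_velocity_um_min": s.median_velocity,
                "n_tracks": s.n_tracks,
            }
        )
        if s.n_units is not None:
            row["n_units"] = s.n_units
        rows.append(row)
    return pd.DataFrame(rows)


def cell_density(counts: Sequence[int], region_volume_um3: float) -> float:
    """Mean cell density over regions, in cells per mm³.

    Each region contributes ``count / volume``; densities are averaged and
    converted with 1 mm³ = 10⁹ µm³.
    """
    if region_volume_um3 <= 0:
        raise ValueError("region volume must be positive")
    if len(counts) == 0:
        raise ComputationError("cell_density undefined for zero regions")
    densities = [c / region_volume_um3 * UM3_PER_MM3 for c in counts]
    return float(np.mean(densities))
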