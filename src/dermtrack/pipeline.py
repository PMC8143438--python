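"""End-to-end orchestration: one declarative config → full analysis run.

A run ingests (or simulates) a cohort of tracks, computes per-track
motility metrics, classifies behaviour, aggregates fov → mouse → group,
runs the between-group statistics, quantifies any SHG stacks, and writes
tidy CSV tables plus a machine-readable JSON report.  Synthetic-mode runs
are deterministic given the seed: repeated invocations produce
byte-identical numeric tables.

Exit-code convention (used by the CLI): 0 success, 2 config error,
3 data error, 4 partial success (some SHG tasks failed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .behaviour import (
    Thresholds,
    classify,
    motile_fraction,
    summaries_to_dataframe,
    summarize_behaviour,
    velocity_distribution,
)
from .errors import ConfigError, DermtrackError
from .motility import metrics_table, metrics_to_dataframe
from .shg import (
    area_fraction,
    crop_region,
    extract_plane,
    read_stack,
    results_to_dataframe,
)
from .stats import (
    TestResult,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    welch_t_battery,
)
from .stats import results_to_dataframe as stats_to_dataframe
from .synthetic import SyntheticConfig, simulate_cohort, simulate_shg_stack
from .track_io import ImagingGeometry, read_tracks

logger = logging.getLogger(__name__)


class GeometryModel(BaseModel):
    field_x: float = Field(300.0, gt=0)
    field_y: float = Field(300.0, gt=0)
    depth: float = Field(100.0, ge=1, le=1000)
    frame_interval: float = Field(60.0, gt=0)
    z_step: float = Field(2.0, gt=0)


class SyntheticGroupModel(BaseModel):
    group: str
    mixture_weights: dict[str, float]
    n_tracks_per_fov: int = Field(20, ge=1)
    n_fov_per_mouse: int = Field(3, ge=1)
    n_mice: int = Field(4, ge=1)
    follicle_anchors: int = Field(3, ge=1)

    @model_validator(mode="after")
    def _weights_sum(self) -> "SyntheticGroupModel":
        total = sum(self.mixture_weights.values())
        if any(w < 0 for w in self.mixture_weights.values()) or abs(total - 1) > 1e-9:
            raise ValueError("mixture_weights must be >= 0 and sum to 1")
        return self


class ThresholdsModel(BaseModel):
    velocity_threshold: float = Field(2.0, gt=0)
    confinement_threshold: float = Field(0.2, gt=0)


class FiltersModel(BaseModel):
    min_points: int = Field(5, ge=0)
    min_duration_min: float = Field(5.0, ge=0)


class ShgTaskModel(BaseModel):
    name: str = "shg"
    path: Optional[str] = None
    synthetic_fill: Optional[float] = Field(None, ge=0, le=1)
    crop_origin_um: tuple[float, float] = (0.0, 0.0)
    crop_size_um: tuple[float, float] = (150.0, 150.0)
    plane: Literal["xy", "zx"] = "xy"
    depth_um: float = 60.0
    y_um: float = 75.0
    method: Literal["otsu", "fixed"] = "otsu"
    threshold: Optional[float] = None
    voxel_size: tuple[float, float, float] = (2.0, 1.0, 1.0)

    @model_validator(mode="after")
    def _one_source(self) -> "ShgTaskModel":
        if (self.path is None) == (self.synthetic_fill is None):
            raise ValueError("exactly one of path / synthetic_fill must be set")
        if self.method == "fixed" and self.threshold is None:
            raise ValueError("fixed method requires a threshold")
        return self


class RunConfig(BaseModel):
    """Declarative description of one analysis run.

    Exactly one input mode is active: ``track_files`` (long-format CSVs
    carrying mouse/fov/group metadata) or ``synthetic_groups``.  All
    thresholds default to the standard analysis parameters (2 µm/min, 0.2,
    150 µm crop, 60 µm depth, α 0.05) and are logged at run time.
    """

    track_files: list[str] = Field(default_factory=list)
    synthetic_groups: list[SyntheticGroupModel] = Field(default_factory=list)
    geometry: GeometryModel = Field(default_factory=GeometryModel)
    thresholds: ThresholdsModel = Field(default_factory=ThresholdsModel)
    filters: FiltersModel = Field(default_factory=FiltersModel)
    histogram_bin_width: float = Field(0.5, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    shg_tasks: list[ShgTaskModel] = Field(default_factory=list)
    output_dir: str = "dermtrack_out"
    seed: int = 0
    verbosity: int = 1

    @model_validator(mode="after")
    def _one_input_mode(self) -> "RunConfig":
        has_files = len(self.track_files) > 0
        has_synth = len(self.synthetic_groups) > 0
        if has_files and has_synth:
            raise ValueError("exactly one input mode: track_files OR synthetic_groups")
        if not has_files and not has_synth and not self.shg_tasks:
            raise ValueError("config describes no work: no tracks and no shg tasks")
        return self


@dataclass
class RunReport:
    """Everything a run produced, plus provenance."""

    per_track: pd.DataFrame
    per_fov: pd.DataFrame
    per_mouse: pd.DataFrame
    per_group: pd.DataFrame
    histograms: dict
    stats: list[TestResult]
    shg: pd.DataFrame
    shg_errors: list[str]
    rejections: pd.DataFrame
    group_summaries: dict
    provenance: dict = field(default_factory=dict)

    @property
    def partial(self) -> bool:
        return len(self.shg_errors) > 0


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from e
    violations = validate_config_dict(raw)
    if violations:
        raise ConfigError("invalid config:\n  " + "\n  ".join(violations))
    return RunConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Return every violation in the config file (empty list means valid)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        return [f"syntax error: {e}"]
    return validate_config_dict(raw)


def validate_config_dict(raw: object) -> list[str]:
    from pydantic import ValidationError as PydanticValidationError

    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    try:
        RunConfig.model_validate(raw)
    except PydanticValidationError as e:
        return [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in e.errors()
        ]
    return []


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _ingest(config: RunConfig) -> list:
    geometry = ImagingGeometry(**config.geometry.model_dump())
    if config.synthetic_groups:
        tracks = []
        for gi, gm in enumerate(config.synthetic_groups):
            sc = SyntheticConfig(
                geometry=geometry,
                mixture_weights=gm.mixture_weights,
                n_tracks_per_fov=gm.n_tracks_per_fov,
                n_fov_per_mouse=gm.n_fov_per_mouse,
                n_mice=gm.n_mice,
                group=gm.group,
                follicle_anchors=gm.follicle_anchors,
                seed=config.seed + gi,
            )
            tracks.extend(simulate_cohort(sc))
        return tracks
    tracks = []
    for path in config.track_files:
        if not Path(path).exists():
            raise DermtrackError(f"track file not found: {path}")
        tracks.extend(read_tracks(path, dialect="long_csv"))
    return tracks


def _group_stats(per_track: pd.DataFrame, per_mouse_pct: pd.DataFrame,
                 alpha: float) -> list[TestResult]:
    """The between-group battery, chosen by the number of groups."""
    groups = sorted(g for g in per_track["group"].unique() if g != "")
    results: list[TestResult] = []
    if len(groups) < 2:
        return results
    velocities = [
        per_track.loc[per_track["group"] == g, "mean_velocity_um_min"].to_numpy()
        for g in groups
    ]
    if len(groups) == 2:
        r = mann_whitney(velocities[0], velocities[1])
        results.append(
            TestResult(r.statistic, r.p_value, r.method, r.n_per_group,
                       comparison=f"velocity: {groups[0]} vs {groups[1]}")
        )
        # quadrant panel: per-mouse percentages, Welch t per quadrant,
        # Holm-Šídák across the four comparisons
        pairs, labels = [], []
        for q in ("Q1", "Q2", "Q3", "Q4"):
            a = per_mouse_pct.loc[per_mouse_pct["group"] == groups[0], q].to_numpy()
            b = per_mouse_pct.loc[per_mouse_pct["group"] == groups[1], q].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                pairs.append((a, b))
                labels.append(f"{q}%: {groups[0]} vs {groups[1]}")
        if pairs:
            results.extend(welch_t_battery(pairs, labels=labels, alpha=alpha))
    else:
        kw = kruskal_wallis(velocities)
        results.append(
            TestResult(kw.statistic, kw.p_value, kw.method, kw.n_per_group,
                       comparison="velocity: " + " / ".join(groups))
        )
        results.extend(
            dunn_posthoc(velocities, comparisons="all_pairs",
                         labels=[f"velocity {g}" for g in groups])
        )
    return results


def _per_mouse_quadrants(per_track: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse quadrant percentages via the fov→mouse hierarchy."""
    rows = []
    for (group, mouse), sub in per_track.groupby(["group", "mouse"], sort=True):
        fov_pcts = []
        for _, fsub in sub.groupby("fov", sort=True):
            n = len(fsub)
            fov_pcts.append(
                {q: 100.0 * (fsub["quadrant"] == q).sum() / n
                 for q in ("Q1", "Q2", "Q3", "Q4")}
            )
        mean_pct = {q: float(pd.Series([f[q] for f in fov_pcts]).mean())
                    for q in ("Q1", "Q2", "Q3", "Q4")}
        rows.append({"group": group, "mouse": mouse, **mean_pct,
                     "n_tracks": len(sub)})
    return pd.DataFrame(rows)


def run(config: RunConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute a full analysis run and write all outputs.

    Stage order: ingest/simulate → metrics → behaviour → statistics → SHG.
    A failing SHG task is recorded and does not abort the track analysis
    (collected-errors model); the report's ``partial`` flag is set instead.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(**config.thresholds.model_dump())
    logger.info(
        "run parameters: velocity threshold %.3g µm/min, confinement %.3g, "
        "filters min_points=%d min_duration=%.3g min, alpha %.3g, seed %d",
        thresholds.velocity_threshold, thresholds.confinement_threshold,
        config.filters.min_points, config.filters.min_duration_min,
        config.alpha, config.seed,
    )

    tracks = _ingest(config)
    logger.info("ingest: %d tracks", len(tracks))
    metrics, rejections = metrics_table(
        tracks,
        min_duration=config.filters.min_duration_min,
        min_points=config.filters.min_points,
    )
    logger.info("metrics: %d accepted, %d rejected", len(metrics), len(rejections))

    per_track = metrics_to_dataframe(metrics)
    histograms: dict = {}
    group_summaries: dict = {}
    stats_results: list[TestResult] = []
    per_fov = per_mouse = per_group = pd.DataFrame()
    per_mouse_pct = pd.DataFrame()
    if metrics:
        per_track["quadrant"] = [classify(m, thresholds) for m in metrics]
        have_hierarchy = {"mouse", "fov", "group"} <= set(per_track.columns)
        if have_hierarchy:
            per_fov = summaries_to_dataframe(
                summarize_behaviour(metrics, thresholds, level="fov"))
            per_mouse = summaries_to_dataframe(
                summarize_behaviour(metrics, thresholds, level="mouse"))
            per_group = summaries_to_dataframe(
                summarize_behaviour(metrics, thresholds, level="group"))
            per_mouse_pct = _per_mouse_quadrants(per_track)
            for g, sub in per_track.groupby("group", sort=True):
                sub_metrics = [m for m in metrics if m.metadata.get("group") == g]
                hist, median_v = velocity_distribution(
                    sub_metrics, bin_width=config.histogram_bin_width)
                histograms[str(g)] = hist
                group_summaries[str(g)] = {
                    "n_tracks": len(sub_metrics),
                    "motile_fraction_pct": motile_fraction(sub_metrics, thresholds),
                    "median_velocity_um_min": median_v,
                }
            stats_results = _group_stats(per_track, per_mouse_pct, config.alpha)
        logger.info("behaviour: %d groups, %d statistical comparisons",
                    len(group_summaries), len(stats_results))

    shg_rows, shg_errors = [], []
    for ti, task in enumerate(config.shg_tasks):
        try:
            if task.synthetic_fill is not None:
                sim = simulate_shg_stack(task.synthetic_fill,
                                         seed=config.seed + 100 + ti)
                stack = sim.stack
            else:
                stack = read_stack(task.path, voxel_size=task.voxel_size)
            stack = crop_region(stack, task.crop_origin_um, task.crop_size_um)
            image, _ = extract_plane(stack, plane=task.plane,
                                     depth_um=task.depth_um, y_um=task.y_um)
            res = area_fraction(
                image, method=task.method, threshold=task.threshold,
                plane=task.plane,
                depth_um=task.depth_um if task.plane == "xy" else task.y_um,
                crop_origin_um=task.crop_origin_um,
                crop_size_um=task.crop_size_um,
            )
            row = {"task": task.name}
            row.update(results_to_dataframe([res]).iloc[0].to_dict())
            shg_rows.append(row)
        except (DermtrackError, OSError, ValueError) as e:
            logger.error("shg task %r failed: %s", task.name, e)
            shg_errors.append(f"{task.name}: {e}")
    shg_df = pd.DataFrame(shg_rows)

    report = RunReport(
        per_track=per_track,
        per_fov=per_fov,
        per_mouse=per_mouse,
        per_group=per_group,
        histograms=histograms,
        stats=stats_results,
        shg=shg_df,
        shg_errors=shg_errors,
        rejections=pd.DataFrame(
            [{"track_id": r.track_id, "reason": r.reason} for r in rejections]
        ),
        group_summaries=group_summaries,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        },
    )
    _write_report(report, out)
    return report


def _write_report(report: RunReport, out: Path) -> None:
    tables = {
        "per_track.csv": report.per_track,
        "per_fov.csv": report.per_fov,
        "per_mouse.csv": report.per_mouse,
        "per_group.csv": report.per_group,
        "shg.csv": report.shg,
        "rejections.csv": report.rejections,
        "stats.csv": stats_to_dataframe(report.stats),
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.9g")
    for g, hist in report.histograms.items():
        hist.to_csv(out / f"velocity_hist_{g}.csv", index=False,
                    float_format="%.9g")
    summary = {
        "groups": report.group_summaries,
        "n_rejected_tracks": len(report.rejections),
        "shg_errors": report.shg_errors,
        "partial": report.partial,
        "provenance": report.provenance,
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
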