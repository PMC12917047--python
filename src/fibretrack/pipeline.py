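"""End-to-end orchestration: simulate/load → register → metrics → lineage →
tidy report tables plus a reproducibility manifest."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lineage import division_records, fate_index_report, cell_cycle_durations
from .motility import (
    DEFAULT_COMIGRATION_OFFSETS_MIN,
    DEFAULT_THRESHOLD_UM_MIN,
    MobilityThreshold,
    derive_threshold,
    sister_comigration,
    summarize_tracks,
)
from .registration import correct_tracks, register_landmark_series
from .synthetic import preset as get_preset
from .synthetic import read_landmarks_csv, simulate_lineages
from . import io as track_io


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``preset`` (simulate a scene) or
    ``tracks_path`` (read a CSV/XML track file, with optional
    ``landmarks_path`` for registration).
    """

    preset: str | None = "wt"
    preset_overrides: dict = field(default_factory=dict)
    n_founders: int = 50
    tracks_path: str | None = None
    landmarks_path: str | None = None
    registration: str = "landmarks"  # landmarks | none
    fate_mode: str = "labels"  # labels | endpoint | live
    threshold_mode: str = "fixed"  # fixed | derived
    comigration_offsets_min: tuple = DEFAULT_COMIGRATION_OFFSETS_MIN
    output_dir: str = "fibretrack_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.tracks_path is None):
            raise PipelineError(
                "config: exactly one of 'preset' and 'tracks_path' must be set"
            )
        if self.registration not in ("landmarks", "none"):
            raise PipelineError(f"config: unknown registration {self.registration!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Outputs under ``config.output_dir``: ``metrics.csv`` (per-cell-segment
    motility), ``divisions.csv``, ``indexes.csv``, ``comigration.csv`` and
    ``manifest.yaml`` (config, package version, seed and exclusion counts);
    identical config + seed give identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "fibretrack_version": __version__,
    }

    # --- input ------------------------------------------------------------
    landmarks = None
    if config.preset is not None:
        try:
            sim_preset = get_preset(config.preset, **config.preset_overrides)
            scene = simulate_lineages(sim_preset, config.n_founders, config.seed)
        except Exception as exc:
            raise PipelineError(f"stage simulate ({config.preset!r}): {exc}") from exc
        tracks, lineage = scene.observed_tracks, scene.lineage
        landmarks = scene.landmarks
    else:
        try:
            reader = (
                track_io.read_tracks_xml
                if str(config.tracks_path).endswith(".xml")
                else track_io.read_tracks_csv
            )
            tracks, lineage = reader(config.tracks_path)
        except Exception as exc:
            raise PipelineError(f"stage read ({config.tracks_path!r}): {exc}") from exc
        if config.landmarks_path:
            landmarks = read_landmarks_csv(config.landmarks_path)

    # --- registration -----------------------------------------------------
    excluded = False
    if config.registration == "landmarks":
        if landmarks is None:
            raise PipelineError("stage register: no landmarks available")
        try:
            frame_to_ref, diag = register_landmark_series(landmarks)
            tracks = correct_tracks(tracks, frame_to_ref)
        except Exception as exc:
            raise PipelineError(f"stage register: {exc}") from exc
        manifest["registration"] = diag
        excluded = diag["motility_excluded"]
        if excluded:
            for t in tracks:
                t.motility_excluded = True

    # --- motility ---------------------------------------------------------
    try:
        if config.threshold_mode == "derived":
            threshold = derive_threshold(tracks)
        else:
            threshold = MobilityThreshold(DEFAULT_THRESHOLD_UM_MIN, "default")
        metrics = summarize_tracks(tracks, lineage, threshold=threshold)
    except Exception as exc:
        raise PipelineError(f"stage metrics: {exc}") from exc
    manifest["threshold_um_min"] = {
        "value": threshold.value,
        "provenance": threshold.provenance,
    }

    # --- lineage ----------------------------------------------------------
    try:
        records = division_records(
            lineage, tracks, fate_mode=config.fate_mode
        )
        divisions = pd.DataFrame(
            [dataclasses.asdict(r) for r in records]
        )
        t_end = max((t.end_t for t in tracks), default=0.0)
        report = fate_index_report(lineage, tracks, 0.0, t_end)
        indexes = pd.DataFrame([dataclasses.asdict(report)])
        comigration = sister_comigration(
            lineage, tracks, config.comigration_offsets_min
        )
        durations = cell_cycle_durations(lineage)
    except Exception as exc:
        raise PipelineError(f"stage lineage: {exc}") from exc

    manifest["counts"] = {
        "n_tracks": len(tracks),
        "n_cells_lineage": len(lineage),
        "n_divisions": len(records),
        "n_orientation_undetermined": int(
            (divisions["orientation"] == "undetermined").sum()
        )
        if len(divisions)
        else 0,
        "n_mode_unclassified": int((divisions["mode"] == "unclassified").sum())
        if len(divisions)
        else 0,
        "n_motility_excluded_segments": int(
            (metrics["mobility_class"] == "excluded").sum()
        )
        if len(metrics)
        else 0,
        "scene_motility_excluded": bool(excluded),
    }

    paths = {
        "metrics": out / "metrics.csv",
        "divisions": out / "divisions.csv",
        "indexes": out / "indexes.csv",
        "comigration": out / "comigration.csv",
        "durations": out / "durations.csv",
        "manifest": out / "manifest.yaml",
    }
    float_fmt = "%.10g"
    metrics.to_csv(paths["metrics"], index=False, float_format=float_fmt)
    divisions.to_csv(paths["divisions"], index=False, float_format=float_fmt)
    indexes.to_csv(paths["indexes"], index=False, float_format=float_fmt)
    comigration.to_csv(paths["comigration"], index=False, float_format=float_fmt)
    durations.to_csv(paths["durations"], index=False, float_format=float_fmt)
    with paths["manifest"].open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def summarize_groups(
    table: pd.DataFrame,
    value: str,
    unit_col: str = "unit",
    group_col: str = "experiment",
) -> pd.DataFrame:
    """Hierarchical descriptive summary: cells → units → groups.

    Per-unit means are computed first, then averaged within each group, so
    unbalanced units are not collapsed into pooled pseudoreplication.
    Empty groups (all-NaN values) are dropped.
    """
    for col in (value, unit_col, group_col):
        if col not in table.columns:
            raise PipelineError(f"summarize: missing column {col!r}")
    unit_means = (
        table.dropna(subset=[value])
        .groupby([group_col, unit_col], sort=True)[value]
        .agg(["mean", "count"])
        .reset_index()
    )
    out = (
        unit_means.groupby(group_col, sort=True)
        .agg(
            mean=("mean", "mean"),
            sd=("mean", "std"),
            n_units=("mean", "size"),
            n_cells=("count", "sum"),
        )
        .reset_index()
    )
    return out
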