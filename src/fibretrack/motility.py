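"""Per-track motility statistics and mobile/static stratification.

For a segment with points p_1..p_N at uniform interval Δt the step distances
are d_i = ||p_{i+1} - p_i||, the net distance D = ||p_N - p_1||, the total
distance Σd_i, the straightness D / Σd_i ∈ [0, 1], the average speed
Σd_i / (t_N - t_1), and the turning angles α_i ∈ [0°, 180°] between
consecutive displacement vectors.  Cells are stratified into mobile and
static by comparing the segment's mean instantaneous speed with a threshold
(default 0.41 μm/min, the empirical split between the high-speed/low-turning
and low-speed/high-turning subpopulations of wild-type cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_MAX_GAP, LineageTree, Track

#: Mobile/static split in μm/min derived from the wild-type reference
#: population (median of log instantaneous speeds).
DEFAULT_THRESHOLD_UM_MIN = 0.41

DEFAULT_COMIGRATION_OFFSETS_MIN = (30.0, 40.0, 50.0, 60.0)


class MotilityError(ValueError):
    """A segment is unusable for the requested motility statistic."""


@dataclass(frozen=True)
class MobilityThreshold:
    """Speed cut-off (μm/min) separating mobile from static cells."""

    value: float
    provenance: str = "default"  # or "derived"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise MotilityError(f"threshold must be positive, got {self.value}")


@dataclass(frozen=True)
class MotilitySummary:
    """Motility statistics of one cell over one segment."""

    cell_id: str
    segment: str  # cell-cycle index, contiguous-chunk index, or "merged"
    n_steps: int
    total_distance: float  # μm
    net_distance: float  # μm
    straightness: float  # unitless, [0, 1]
    average_speed_um_h: float
    mean_step_speed_um_min: float
    mean_turning_angle_deg: float  # NaN when < 2 usable steps
    mobility_class: str = "unclassified"  # mobile | static | excluded


def step_metrics(segment: Track) -> pd.DataFrame:
    """Per-step distances d_i and instantaneous speeds of one segment.

    Returns a DataFrame with columns ``d_um``, ``speed_um_min`` and
    ``speed_um_h`` (n−1 rows for n points; empty for a single point).
    """
    if len(segment) < 2:
        return pd.DataFrame(columns=["d_um", "speed_um_min", "speed_um_h"])
    steps = np.diff(segment.xyz, axis=0)
    dt_min = np.diff(segment.t)
    d = np.linalg.norm(steps, axis=1)
    speed = d / dt_min
    return pd.DataFrame(
        {"d_um": d, "speed_um_min": speed, "speed_um_h": speed * 60.0}
    )


def turning_angles(segment: Track) -> np.ndarray:
    """Turning angles α_i (degrees) between consecutive displacements.

    0° is straight-ahead motion, 180° a full reversal.  Steps of zero
    length have no direction and are skipped.
    """
    if len(segment) < 3:
        return np.array([])
    steps = np.diff(segment.xyz, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    keep = lengths > 0
    steps, lengths = steps[keep], lengths[keep]
    if len(steps) < 2:
        return np.array([])
    cosang = np.sum(steps[:-1] * steps[1:], axis=1) / (lengths[:-1] * lengths[1:])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def path_summary(segment: Track, label: str = "0") -> MotilitySummary:
    """Distance, straightness, speed and turning statistics of one segment."""
    if len(segment) < 2:
        raise MotilityError(f"cell {segment.cell_id!r}: segment has < 2 points")
    duration_min = segment.end_t - segment.start_t
    if duration_min <= 0:
        raise MotilityError(f"cell {segment.cell_id!r}: zero-duration segment")
    steps = step_metrics(segment)
    total = float(steps["d_um"].sum())
    net = float(np.linalg.norm(segment.xyz[-1] - segment.xyz[0]))
    angles = turning_angles(segment)
    return MotilitySummary(
        cell_id=segment.cell_id,
        segment=label,
        n_steps=len(steps),
        total_distance=total,
        net_distance=net,
        straightness=net / total if total > 0 else 0.0,
        average_speed_um_h=total / duration_min * 60.0,
        mean_step_speed_um_min=float(steps["speed_um_min"].mean()),
        mean_turning_angle_deg=float(angles.mean()) if angles.size else float("nan"),
        mobility_class="excluded" if segment.motility_excluded else "unclassified",
    )


def derive_threshold(reference_tracks: Iterable[Track]) -> MobilityThreshold:
    """Threshold from a reference population: the exponential of the median
    log instantaneous speed (= the median speed), in μm/min.

    Only strictly positive steps enter; with a bimodal speed mixture and
    comparable subpopulation sizes the pooled median lands between the
    modes.
    """
    speeds = []
    for track in reference_tracks:
        s = step_metrics(track)["speed_um_min"].to_numpy()
        speeds.append(s[s > 0])
    pooled = np.concatenate(speeds) if speeds else np.array([])
    if pooled.size == 0:
        raise MotilityError("no positive steps in the reference population")
    return MobilityThreshold(
        value=float(np.exp(np.median(np.log(pooled)))), provenance="derived"
    )


def classify_mobility(
    summary: MotilitySummary, threshold: MobilityThreshold | float
) -> MotilitySummary:
    """Attach the mobile/static class; registration-excluded segments keep
    class ``excluded``."""
    value = threshold.value if isinstance(threshold, MobilityThreshold) else threshold
    if summary.mobility_class == "excluded":
        return summary
    cls = "mobile" if summary.mean_step_speed_um_min >= value else "static"
    return MotilitySummary(**{**summary.__dict__, "mobility_class": cls})


def _cycle_segments(
    track: Track, lineage: LineageTree | None
) -> list[tuple[str, Track]]:
    """One segment per cell (birth to division/censoring).

    With the lineage available the classification unit is the cell-cycle
    segment: each cell id already spans exactly one cycle, so the whole
    track is the segment, labelled by its generation index.
    """
    if lineage is not None and track.cell_id in lineage:
        gen = lineage.generation_of(track.cell_id)
        return [(str(gen), track)]
    return [("0", track)]


def summarize_tracks(
    tracks: Sequence[Track],
    lineage: LineageTree | None = None,
    threshold: MobilityThreshold | float | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    merged: bool = True,
) -> pd.DataFrame:
    """Tidy motility table: one row per (cell_id, segment).

    Segments are cell cycles (labelled by generation when a lineage is
    given); gaps longer than ``max_gap`` frames split a segment further.
    When ``merged`` is true an additional "merged" row pools the step sums
    of all of a cell's segments.  When ``threshold`` is given the
    ``mobility_class`` column is filled in.
    """
    rows: list[MotilitySummary] = []
    durations: dict[int, float] = {}
    for track in tracks:
        for label, seg in _cycle_segments(track, lineage):
            chunks = seg.segments(max_gap)
            for j, chunk in enumerate(chunks):
                if len(chunk) < 2:
                    continue
                sublabel = label if len(chunks) == 1 else f"{label}.{j}"
                durations[len(rows)] = chunk.end_t - chunk.start_t
                rows.append(path_summary(chunk, label=sublabel))
    if merged:
        by_cell: dict[str, list[int]] = {}
        for i, r in enumerate(rows):
            by_cell.setdefault(r.cell_id, []).append(i)
        for cid, idx in by_cell.items():
            if len(idx) < 2:
                continue
            segs = [rows[i] for i in idx]
            total = sum(s.total_distance for s in segs)
            n = sum(s.n_steps for s in segs)
            dur_min = sum(durations[i] for i in idx)
            angles = [
                s.mean_turning_angle_deg
                for s in segs
                if not np.isnan(s.mean_turning_angle_deg)
            ]
            rows.append(
                MotilitySummary(
                    cell_id=cid,
                    segment="merged",
                    n_steps=n,
                    total_distance=total,
                    net_distance=float("nan"),
                    straightness=float("nan"),
                    average_speed_um_h=total / dur_min * 60.0 if dur_min else 0.0,
                    mean_step_speed_um_min=total / dur_min if dur_min else 0.0,
                    mean_turning_angle_deg=float(np.mean(angles)) if angles else float("nan"),
                    mobility_class="excluded"
                    if any(s.mobility_class == "excluded" for s in segs)
                    else "unclassified",
                )
            )
    if threshold is not None:
        rows = [classify_mobility(r, threshold) for r in rows]
    return pd.DataFrame([r.__dict__ for r in rows])


def mobile_fraction(summaries: pd.DataFrame, segment: str | None = None) -> float:
    """Fraction of classified segments that are mobile (excluded ones do not
    count in the denominator)."""
    df = summaries
    if segment is not None:
        df = df[df["segment"] == segment]
    df = df[df["mobility_class"].isin(["mobile", "static"])]
    if len(df) == 0:
        raise MotilityError("no classified segments")
    return float((df["mobility_class"] == "mobile").mean())


def sister_comigration(
    lineage: LineageTree,
    tracks: Sequence[Track],
    offsets_min: Sequence[float] = DEFAULT_COMIGRATION_OFFSETS_MIN,
) -> pd.DataFrame:
    """Fraction of divisions whose sisters co-migrate, per time offset.

    For each division and offset τ, v_k is the displacement of daughter k
    at t_div + τ relative to the mitosis site (the mother's last position).
    Sisters co-migrate when v_a · v_b > 0 (inter-vector angle < 90°; an
    exactly orthogonal pair counts as opposite).  Divisions whose daughters
    are not tracked to t_div + τ are dropped from that offset's denominator.
    """
    by_id = {t.cell_id: t for t in tracks}
    records = []
    for tau in offsets_min:
        n_total = n_used = n_co = 0
        for mother in lineage.divisions():
            n_total += 1
            if mother not in by_id:
                continue
            site = by_id[mother].xyz[-1]
            t_div = lineage.nodes[mother].end_t
            vs = []
            for d in lineage.daughters(mother):
                track = by_id.get(d)
                pos = track.position_at(t_div + tau) if track is not None else None
                if pos is not None:
                    vs.append(pos - site)
            if len(vs) != 2:
                continue
            n_used += 1
            if float(np.dot(vs[0], vs[1])) > 0:
                n_co += 1
        records.append(
            {
                "offset_min": tau,
                "n_divisions": n_total,
                "n_evaluable": n_used,
                "n_comigrating": n_co,
                "fraction_comigrating": n_co / n_used if n_used else float("nan"),
            }
        )
    return pd.DataFrame(records)
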