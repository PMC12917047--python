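"""Cell-cycle timing, division-mode and orientation classification, and
population fate indexes.

Division modes follow the daughter-fate rule: both daughters MYOG-negative
is a symmetric proliferative division (SCDp), both positive symmetric
differentiative (SCDd), one of each asymmetric (ACD).  Orientation relative
to the myofibre is read from the daughters' fibre-contact flags at mitosis:
both in contact is planar, exactly one detached perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import LineageTree, ShapeDescriptor, Track

DIVISION_MODES = ("SCDp", "SCDd", "ACD", "unclassified")
ORIENTATIONS = ("planar", "perpendicular", "undetermined")

#: Daughters must be distinguishable within this window after mitosis
#: (empirical post-mitotic disconnection time).
SISTER_WINDOW_H = 2.3


class LineageAnalysisError(ValueError):
    """Invalid lineage input for a fate/timing computation."""


@dataclass(frozen=True)
class DivisionRecord:
    mother_id: str
    daughter_ids: tuple[str, str]
    division_t_h: float
    generation: int
    mode: str = "unclassified"
    orientation: str = "undetermined"


@dataclass(frozen=True)
class FateIndexReport:
    differentiation_index: float  # fraction in [0, 1], NaN if undefined
    proliferation_index: float  # ratio >= 0
    n_initial: int
    n_final: int
    n_fate_known: int
    n_fate_unknown: int
    t_ref_h: float
    t_end_h: float


def classify_division(fate_a: str, fate_b: str) -> str:
    """Map a pair of daughter MYOG fates to a division mode.

    (negative, negative) → SCDp, (positive, positive) → SCDd, mixed → ACD;
    any unknown fate leaves the division unclassified.
    """
    pair = {fate_a, fate_b}
    if "unknown" in pair or not pair <= {"negative", "positive"}:
        return "unclassified"
    if pair == {"negative"}:
        return "SCDp"
    if pair == {"positive"}:
        return "SCDd"
    return "ACD"


def fate_at_classification(
    track: Track,
    division_t_min: float,
    window_end_min: float | None = None,
    mode: str = "endpoint",
) -> str:
    """MYOG fate of a daughter cell for division classification.

    ``mode="endpoint"`` reads the status at the cell's last observation
    (retrospective immunostain); ``mode="live"`` calls the cell positive if
    any observation between the division and ``window_end_min`` (its own
    next division, or the movie end) is positive — the live-reporter
    convention, which tolerates the delayed marker onset.
    """
    if mode not in ("endpoint", "live"):
        raise LineageAnalysisError(f"unknown fate mode {mode!r}")
    if np.all(track.myog == "unknown"):
        return "unknown"
    if mode == "endpoint":
        return track.myog_status_at(track.end_t)
    onset = track.myog_positive_from()
    end = window_end_min if window_end_min is not None else track.end_t
    if onset is not None and division_t_min - 1e-9 <= onset <= end + 1e-9:
        return "positive"
    return "negative"


def division_orientation(contact_a: str, contact_b: str) -> str:
    """Planar when both daughters touch the fibre at mitosis, perpendicular
    when exactly one has lost contact, undetermined when either is unknown."""
    pair = (contact_a, contact_b)
    if "unknown" in pair:
        return "undetermined"
    n_contact = sum(c == "contact" for c in pair)
    return "planar" if n_contact == 2 else "perpendicular"


def _contact_at_mitosis(track: Track, n_frames: int = 2) -> str:
    """Daughter fibre-contact flag within the first post-mitotic frames."""
    flags = [f for f in track.fibre_contact[:n_frames] if f != "unknown"]
    if not flags:
        return "unknown"
    return "no_contact" if "no_contact" in flags else "contact"


def division_records(
    lineage: LineageTree,
    tracks: Sequence[Track] | None = None,
    fate_mode: str = "labels",
    orientation_frames: int = 2,
) -> list[DivisionRecord]:
    """One record per completed division, with mode and orientation.

    ``fate_mode="labels"`` classifies from the fate labels stored on the
    lineage nodes; ``"endpoint"`` and ``"live"`` re-derive daughter fates
    from track MYOG annotations (``tracks`` required).
    """
    by_id = {t.cell_id: t for t in tracks} if tracks else {}
    if fate_mode != "labels" and not by_id:
        raise LineageAnalysisError(f"fate mode {fate_mode!r} requires tracks")
    records = []
    for mother in lineage.divisions():
        d_a, d_b = lineage.daughters(mother)
        node = lineage.nodes[mother]
        fates = []
        contacts = []
        for d in (d_a, d_b):
            if fate_mode == "labels":
                fates.append(lineage.nodes[d].fate)
            elif d in by_id:
                fates.append(
                    fate_at_classification(
                        by_id[d],
                        node.end_t,
                        window_end_min=lineage.nodes[d].end_t,
                        mode=fate_mode,
                    )
                )
            else:
                fates.append("unknown")
            contacts.append(
                _contact_at_mitosis(by_id[d], orientation_frames)
                if d in by_id
                else "unknown"
            )
        records.append(
            DivisionRecord(
                mother_id=mother,
                daughter_ids=(d_a, d_b),
                division_t_h=node.end_t / 60.0,
                generation=lineage.generation_of(mother),
                mode=classify_division(*fates),
                orientation=division_orientation(*contacts),
            )
        )
    return records


def mode_fractions(records: Sequence[DivisionRecord]) -> dict[str, float]:
    """Fractions of SCDp/SCDd/ACD over the classified divisions (they sum
    to 1); unclassified divisions are excluded from the denominator."""
    classified = [r for r in records if r.mode != "unclassified"]
    if not classified:
        raise LineageAnalysisError("no classified divisions")
    n = len(classified)
    return {
        mode: sum(r.mode == mode for r in classified) / n
        for mode in ("SCDp", "SCDd", "ACD")
    }


def cell_cycle_durations(lineage: LineageTree) -> pd.DataFrame:
    """Cell-cycle durations (h) per generation index.

    Generation 1 runs from observation start to the first division;
    generation k ≥ 2 is the inter-division interval.  Cells that never
    divide are censored: excluded from duration means but counted.
    """
    t_max = max((n.end_t for n in lineage.nodes.values()), default=0.0)
    rows = []
    for cid, node in lineage.nodes.items():
        if node.end_t < node.birth_t:
            raise LineageAnalysisError(f"cell {cid!r}: division before birth")
        rows.append(
            {
                "cell_id": cid,
                "generation": lineage.generation_of(cid),
                "duration_h": (node.end_t - node.birth_t) / 60.0,
                "censored": node.end_reason != "division",
                # observation window: a division could only be seen if it
                # fell within this many hours of the cell's birth
                "window_h": (t_max - node.birth_t) / 60.0,
            }
        )
    return pd.DataFrame(rows)


def mean_cycle_duration(
    durations: pd.DataFrame,
    generation: int | None = None,
    min_generation: int | None = None,
    censoring_corrected: bool = False,
) -> float:
    """Mean cycle duration (h) over completed (non-censored) cycles.

    The plain mean of completed cycles underestimates the population mean
    when cycles are right-censored by the movie end: a cell born late can
    only contribute if its cycle happened to be short.  With
    ``censoring_corrected=True`` the mean is instead the location parameter
    of a normal duration model fitted by maximum likelihood to the
    completed durations, each conditioned on falling inside the cell's own
    observation window (a standard truncated-likelihood correction).
    """
    df = durations[~durations["censored"]]
    if generation is not None:
        df = df[df["generation"] == generation]
    if min_generation is not None:
        df = df[df["generation"] >= min_generation]
    if len(df) == 0:
        raise LineageAnalysisError("no completed cycles in selection")
    if not censoring_corrected:
        return float(df["duration_h"].mean())
    return _truncated_normal_mean(
        df["duration_h"].to_numpy(), df["window_h"].to_numpy()
    )


def _truncated_normal_mean(durations: np.ndarray, windows: np.ndarray) -> float:
    """MLE of μ for durations D ~ N(μ, σ²) observed only when D < window."""
    from scipy import optimize, stats

    d, c = np.asarray(durations, float), np.asarray(windows, float)

    def nll(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        logf = stats.norm.logpdf(d, mu, sigma)
        logF = stats.norm.logcdf(c, mu, sigma)
        return -(logf - logF).sum()

    x0 = np.array([d.mean(), np.log(max(d.std(), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead")
    return float(res.x[0])


def _alive_at(lineage: LineageTree, t_min: float) -> list[str]:
    return [
        cid
        for cid, node in lineage.nodes.items()
        if node.birth_t - 1e-9 <= t_min
        and (t_min <= node.end_t + 1e-9 or node.end_reason == "censored")
    ]


def differentiation_index(
    lineage: LineageTree,
    tracks: Sequence[Track],
    t_min: float,
) -> tuple[float, int, int]:
    """Fraction of MYOG-positive cells among fate-known cells alive at
    ``t_min`` (minutes).  Returns (index, n_known, n_unknown); the index is
    NaN when no cell has a known status."""
    by_id = {t.cell_id: t for t in tracks}
    n_pos = n_known = n_unknown = 0
    for cid in _alive_at(lineage, t_min):
        track = by_id.get(cid)
        status = track.myog_status_at(t_min) if track is not None else "unknown"
        if status == "unknown":
            n_unknown += 1
        else:
            n_known += 1
            n_pos += status == "positive"
    index = n_pos / n_known if n_known else float("nan")
    return index, n_known, n_unknown


def proliferation_index(
    lineage: LineageTree, t_ref_min: float, t_end_min: float
) -> FateIndexReport:
    """Count ratio N(t_end) / N(t_ref); cells lost before a time point do
    not count at that time point."""
    n_ref = len(_alive_at(lineage, t_ref_min))
    n_end = len(_alive_at(lineage, t_end_min))
    if n_ref == 0:
        raise LineageAnalysisError(f"no cells alive at reference time {t_ref_min} min")
    return FateIndexReport(
        differentiation_index=float("nan"),
        proliferation_index=n_end / n_ref,
        n_initial=n_ref,
        n_final=n_end,
        n_fate_known=0,
        n_fate_unknown=0,
        t_ref_h=t_ref_min / 60.0,
        t_end_h=t_end_min / 60.0,
    )


def fate_index_report(
    lineage: LineageTree,
    tracks: Sequence[Track],
    t_ref_min: float,
    t_end_min: float,
) -> FateIndexReport:
    """Differentiation and proliferation indexes over one scene."""
    prolif = proliferation_index(lineage, t_ref_min, t_end_min)
    diff, n_known, n_unknown = differentiation_index(lineage, tracks, t_end_min)
    return FateIndexReport(
        differentiation_index=diff,
        proliferation_index=prolif.proliferation_index,
        n_initial=prolif.n_initial,
        n_final=prolif.n_final,
        n_fate_known=n_known,
        n_fate_unknown=n_unknown,
        t_ref_h=t_ref_min / 60.0,
        t_end_h=t_end_min / 60.0,
    )


def myog_onset_and_redivision(
    lineage: LineageTree, tracks: Sequence[Track]
) -> dict:
    """Live-reporter kinetics summaries.

    Returns marker-onset delays after the cell's own birth (h), the
    fraction of MYOG-positive cells that divide again, and the fraction of
    SCDd divisions whose mother was MYOG-negative at division, each with
    its denominator.
    """
    by_id = {t.cell_id: t for t in tracks}
    onsets = []
    n_pos = n_redivide = 0
    n_scdd = n_scdd_neg_mother = 0
    for cid, node in lineage.nodes.items():
        track = by_id.get(cid)
        onset = track.myog_positive_from() if track is not None else None
        if onset is not None:
            if node.parent_id is not None:
                onsets.append((onset - node.birth_t) / 60.0)
            n_pos += 1
            n_redivide += node.end_reason == "division"
    for mother in lineage.divisions():
        fates = [lineage.nodes[d].fate for d in lineage.daughters(mother)]
        if classify_division(*fates) != "SCDd":
            continue
        n_scdd += 1
        track = by_id.get(mother)
        if track is not None:
            status = track.myog_status_at(lineage.nodes[mother].end_t)
            n_scdd_neg_mother += status == "negative"
    return {
        "onset_delays_h": onsets,
        "redivision_fraction": n_redivide / n_pos if n_pos else float("nan"),
        "n_positive": n_pos,
        "scdd_negative_mother_fraction": n_scdd_neg_mother / n_scdd
        if n_scdd
        else float("nan"),
        "n_scdd": n_scdd,
    }


def shape_metrics(shape: ShapeDescriptor) -> dict:
    """Circularity 4π·area/perimeter² (clipped to [0, 1], round = 1),
    aspect ratio max/min diameter, and the myotube call (aspect ratio > 2)."""
    circularity = 4.0 * np.pi * shape.area / shape.perimeter**2
    aspect = shape.max_diameter / shape.min_diameter
    return {
        "circularity": float(np.clip(circularity, 0.0, 1.0)),
        "aspect_ratio": float(aspect),
        "is_myotube": bool(aspect > 2.0),
    }
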