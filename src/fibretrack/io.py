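"""Readers and writers for the supported track file formats.

Two formats are supported: a tabular CSV (one row per observation) and a
subset of the TrackMate XML dialect (spots plus link edges, with divisions
encoded as a spot with two outgoing edges).  Both read into the same
in-memory structures: a list of :class:`~fibretrack.model.Track` and a
:class:`~fibretrack.model.LineageTree`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from lxml import etree

from .model import (
    CONTACT_STATES,
    MYOG_STATES,
    LineageNode,
    LineageTree,
    Track,
    TrackValidationError,
)

CSV_COLUMNS = (
    "cell_id",
    "parent_id",
    "frame",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
    "myog",
    "fibre_contact",
)

# Written precision preserves positions to well below 1e-6 μm on the scales
# of a microscopy field, so write -> read -> write is byte-stable.
_FMT = "%.10g"


class TrackParseError(ValueError):
    """A track file is malformed or structurally invalid."""


def _fate_from_track(track: Track) -> str:
    if track.myog_positive_from() is not None:
        return "positive"
    if np.all(track.myog == "unknown"):
        return "unknown"
    return "negative"


def _build_lineage(tracks: list[Track], parents: dict[str, str | None]) -> LineageTree:
    """Assemble a lineage from per-cell parent links.

    A daughter's birth time is its mother's division time (the mother's last
    observation); a mother with daughters ends by division, any other cell is
    censored at its last observation.
    """
    by_id = {t.cell_id: t for t in tracks}
    children: dict[str, list[str]] = {}
    for cid, pid in parents.items():
        if pid is not None:
            children.setdefault(pid, []).append(cid)
    lineage = LineageTree()
    for track in tracks:
        cid = track.cell_id
        pid = parents.get(cid)
        if pid is not None and pid not in by_id:
            raise TrackParseError(f"cell {cid!r}: unknown parent {pid!r}")
        birth = by_id[pid].end_t if pid is not None else track.start_t
        lineage.add(
            LineageNode(
                cell_id=cid,
                parent_id=pid,
                birth_t=birth,
                end_t=track.end_t,
                end_reason="division" if len(children.get(cid, [])) == 2 else "censored",
                fate=_fate_from_track(track),
            )
        )
    try:
        lineage.validate()
    except TrackValidationError as exc:
        raise TrackParseError(str(exc)) from exc
    return lineage


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def read_tracks_csv(path: str | Path) -> tuple[list[Track], LineageTree]:
    """Read the tabular track format.

    Mandatory columns: ``cell_id, parent_id, frame, t_min, x_um, y_um, z_um,
    myog, fibre_contact``.  Unknown annotation values map to ``"unknown"``;
    an empty ``parent_id`` marks a lineage root.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrackParseError(f"{path}: empty file")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TrackParseError(f"{path}: missing columns {missing}")
        rows = list(reader)

    order: list[str] = []
    per_cell: dict[str, dict[str, list]] = {}
    parents: dict[str, str | None] = {}
    for row in rows:
        cid = row["cell_id"]
        if cid not in per_cell:
            order.append(cid)
            per_cell[cid] = {"frame": [], "t": [], "xyz": [], "myog": [], "fc": []}
            parents[cid] = row["parent_id"] or None
        rec = per_cell[cid]
        rec["frame"].append(int(row["frame"]))
        rec["t"].append(float(row["t_min"]))
        rec["xyz"].append(
            (float(row["x_um"]), float(row["y_um"]), float(row["z_um"] or 0.0))
        )
        rec["myog"].append(row["myog"] if row["myog"] in MYOG_STATES else "unknown")
        rec["fc"].append(
            row["fibre_contact"] if row["fibre_contact"] in CONTACT_STATES else "unknown"
        )

    tracks = []
    for cid in order:
        rec = per_cell[cid]
        frames = np.array(rec["frame"])
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise TrackParseError(f"{path}: cell {cid!r} frames not strictly increasing")
        steps = np.diff(rec["t"])
        dts = steps / np.diff(frames) if len(frames) > 1 else np.array([])
        dt = float(dts[0]) if dts.size else float(rec["t"][0] / frames[0]) if frames[0] else 1.0
        try:
            tracks.append(
                Track(
                    cell_id=cid,
                    dt=dt,
                    frames=frames,
                    xyz=np.array(rec["xyz"]),
                    t=np.array(rec["t"]),
                    myog=np.array(rec["myog"], dtype=object),
                    fibre_contact=np.array(rec["fc"], dtype=object),
                )
            )
        except TrackValidationError as exc:
            raise TrackParseError(f"{path}: {exc}") from exc
    return tracks, _build_lineage(tracks, parents)


def write_tracks_csv(
    tracks: list[Track], lineage: LineageTree | None, path: str | Path
) -> Path:
    """Write tracks (and parent links from ``lineage``) as tidy CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for track in tracks:
            pid = ""
            if lineage is not None and track.cell_id in lineage:
                pid = lineage.nodes[track.cell_id].parent_id or ""
            for i in range(len(track)):
                writer.writerow(
                    [
                        track.cell_id,
                        pid,
                        int(track.frames[i]),
                        _FMT % track.t[i],
                        _FMT % track.xyz[i, 0],
                        _FMT % track.xyz[i, 1],
                        _FMT % track.xyz[i, 2],
                        track.myog[i],
                        track.fibre_contact[i],
                    ]
                )
    return path


# ---------------------------------------------------------------------------
# TrackMate-dialect XML
# ---------------------------------------------------------------------------


def read_tracks_xml(path: str | Path) -> tuple[list[Track], LineageTree]:
    """Read the supported TrackMate XML subset.

    Spots carry ``ID``, ``FRAME`` and ``POSITION_X/Y/Z``; ``Edge`` elements
    link spots into tracks, and a spot with two outgoing edges is a
    division.  Positions are converted to μm with the spatial calibration in
    ``Settings/ImageData`` when the model's units are pixels.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrackParseError(f"{path}: malformed XML ({exc})") from exc
    root = tree.getroot()
    model = root.find("Model")
    if model is None:
        raise TrackParseError(f"{path}: missing <Model> element")

    image_data = root.find("Settings/ImageData")
    pixel = np.ones(3)
    dt = 1.0
    if image_data is not None:
        pixel = np.array(
            [
                float(image_data.get("pixelwidth", 1.0)),
                float(image_data.get("pixelheight", 1.0)),
                float(image_data.get("voxeldepth", 1.0)),
            ]
        )
        dt = float(image_data.get("timeinterval", 1.0))
    in_pixels = model.get("spatialunits", "micron").lower() in ("pixel", "pixels")

    spots: dict[int, dict] = {}
    for spot in model.iterfind("AllSpots/SpotsInFrame/Spot"):
        sid = spot.get("ID")
        if sid is None:
            raise TrackParseError(f"{path}: <Spot> without ID")
        pos = np.array(
            [
                float(spot.get("POSITION_X", 0.0)),
                float(spot.get("POSITION_Y", 0.0)),
                float(spot.get("POSITION_Z", 0.0)),
            ]
        )
        if in_pixels:
            pos = pos * pixel
        spots[int(sid)] = {
            "frame": int(spot.get("FRAME")),
            "pos": pos,
            "myog": spot.get("MYOG", "unknown"),
            "fc": spot.get("FIBRE_CONTACT", "unknown"),
        }

    out_edges: dict[int, list[int]] = {}
    in_deg: dict[int, int] = {}
    for edge in model.iterfind("AllTracks/Track/Edge"):
        src = int(edge.get("SPOT_SOURCE_ID"))
        tgt = int(edge.get("SPOT_TARGET_ID"))
        for sid in (src, tgt):
            if sid not in spots:
                raise TrackParseError(f"{path}: edge references unknown spot {sid}")
        out_edges.setdefault(src, []).append(tgt)
        in_deg[tgt] = in_deg.get(tgt, 0) + 1
        if len(out_edges[src]) > 2:
            raise TrackParseError(
                f"{path}: spot {src} has more than two daughters"
            )

    # Decompose the spot graph into unbranched chains (= cells).
    tracks: list[Track] = []
    parents: dict[str, str | None] = {}
    starts = [
        (sid, None)
        for sid in sorted(spots)
        if in_deg.get(sid, 0) == 0
    ]
    visited: set[int] = set()
    queue = list(starts)
    while queue:
        sid, parent_cell = queue.pop(0)
        chain = [sid]
        visited.add(sid)
        while len(out_edges.get(chain[-1], [])) == 1:
            nxt = out_edges[chain[-1]][0]
            if nxt in visited:
                raise TrackParseError(f"{path}: cyclic link at spot {nxt}")
            chain.append(nxt)
            visited.add(nxt)
        cid = f"c{chain[0]}"
        parents[cid] = parent_cell
        recs = [spots[s] for s in chain]
        order = np.argsort([r["frame"] for r in recs], kind="stable")
        recs = [recs[i] for i in order]
        tracks.append(
            Track(
                cell_id=cid,
                dt=dt,
                frames=np.array([r["frame"] for r in recs]),
                xyz=np.array([r["pos"] for r in recs]),
                myog=np.array(
                    [r["myog"] if r["myog"] in MYOG_STATES else "unknown" for r in recs],
                    dtype=object,
                ),
                fibre_contact=np.array(
                    [r["fc"] if r["fc"] in CONTACT_STATES else "unknown" for r in recs],
                    dtype=object,
                ),
            )
        )
        for daughter in out_edges.get(chain[-1], []):
            if daughter in visited:
                raise TrackParseError(f"{path}: cyclic link at spot {daughter}")
            queue.append((daughter, cid))

    return tracks, _build_lineage(tracks, parents)


def write_tracks_xml(
    tracks: list[Track], lineage: LineageTree | None, path: str | Path
) -> Path:
    """Write tracks in the TrackMate XML subset read by :func:`read_tracks_xml`."""
    path = Path(path)
    dt = tracks[0].dt if tracks else 1.0
    root = etree.Element("TrackMate", version="7")
    model = etree.SubElement(
        root, "Model", spatialunits="micron", timeunits="min"
    )
    all_spots = etree.SubElement(model, "AllSpots")
    all_tracks = etree.SubElement(model, "AllTracks")

    spot_ids: dict[tuple[str, int], int] = {}
    next_id = 0
    by_frame: dict[int, list[tuple[int, Track, int]]] = {}
    for track in tracks:
        for i, frame in enumerate(track.frames):
            spot_ids[(track.cell_id, i)] = next_id
            by_frame.setdefault(int(frame), []).append((next_id, track, i))
            next_id += 1
    for frame in sorted(by_frame):
        sif = etree.SubElement(all_spots, "SpotsInFrame", frame=str(frame))
        for sid, track, i in by_frame[frame]:
            attrs = {
                "ID": str(sid),
                "name": f"{track.cell_id}_{frame}",
                "FRAME": str(frame),
                "POSITION_X": _FMT % track.xyz[i, 0],
                "POSITION_Y": _FMT % track.xyz[i, 1],
                "POSITION_Z": _FMT % track.xyz[i, 2],
                "POSITION_T": _FMT % track.t[i],
            }
            if track.myog[i] != "unknown":
                attrs["MYOG"] = str(track.myog[i])
            if track.fibre_contact[i] != "unknown":
                attrs["FIBRE_CONTACT"] = str(track.fibre_contact[i])
            etree.SubElement(sif, "Spot", **attrs)
    all_spots.set("nspots", str(next_id))

    by_id = {t.cell_id: t for t in tracks}
    roots = (
        lineage.roots
        if lineage is not None
        else [t.cell_id for t in tracks]
    )
    for k, root_cell in enumerate(r for r in roots if r in by_id):
        trk = etree.SubElement(all_tracks, "Track", TRACK_ID=str(k), name=f"Track_{k}")
        stack = [root_cell]
        while stack:
            cid = stack.pop()
            track = by_id[cid]
            for i in range(len(track) - 1):
                etree.SubElement(
                    trk,
                    "Edge",
                    SPOT_SOURCE_ID=str(spot_ids[(cid, i)]),
                    SPOT_TARGET_ID=str(spot_ids[(cid, i + 1)]),
                )
            if lineage is not None:
                for daughter in lineage.daughters(cid):
                    if daughter not in by_id:
                        continue
                    etree.SubElement(
                        trk,
                        "Edge",
                        SPOT_SOURCE_ID=str(spot_ids[(cid, len(track) - 1)]),
                        SPOT_TARGET_ID=str(spot_ids[(daughter, 0)]),
                    )
                    stack.append(daughter)

    settings = etree.SubElement(root, "Settings")
    etree.SubElement(
        settings,
        "ImageData",
        pixelwidth="1.0",
        pixelheight="1.0",
        voxeldepth="1.0",
        timeinterval=_FMT % dt,
    )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )
    return path
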