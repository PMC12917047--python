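"""Domain types for cell tracks and lineage trees.

All coordinates are micrometres in a right-handed frame with the origin at
the image corner; frames are 0-based integers and time is minutes (hours
only at reporting time).  A :class:`Track` holds the timed positions of one
cell; a :class:`LineageTree` links cells through divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

MYOG_STATES = ("negative", "positive", "unknown")
CONTACT_STATES = ("contact", "no_contact", "unknown")
END_REASONS = ("division", "censored", "lost")

#: Gaps longer than this many missing frames split a track into segments.
DEFAULT_MAX_GAP = 3


class TrackValidationError(ValueError):
    """A track or lineage violates a structural invariant."""


@dataclass(frozen=True)
class TimedPoint:
    """One observation of a cell: frame index, time (min) and position (μm)."""

    frame: int
    t: float
    x: float
    y: float
    z: float = 0.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track:
    """Time-ordered positions of a single cell.

    Parameters
    ----------
    cell_id
        Identifier, unique within a scene.
    dt
        Frame interval Δt in minutes.
    frames, xyz
        Strictly increasing frame indices and the matching (n, 3) positions
        in μm.  ``t`` is derived as ``frames * dt`` unless given explicitly.
    myog, fibre_contact
        Per-point annotations; default ``"unknown"``.
    """

    cell_id: str
    dt: float
    frames: np.ndarray
    xyz: np.ndarray
    t: np.ndarray | None = None
    myog: np.ndarray | None = None
    fibre_contact: np.ndarray | None = None
    motility_excluded: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        n = len(self.frames)
        if n == 0:
            raise TrackValidationError(f"track {self.cell_id!r} has no points")
        if self.xyz.shape != (n, 3):
            raise TrackValidationError(
                f"track {self.cell_id!r}: xyz shape {self.xyz.shape} != ({n}, 3)"
            )
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise TrackValidationError(
                f"track {self.cell_id!r}: frames not strictly increasing"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise TrackValidationError(f"track {self.cell_id!r}: non-finite coordinates")
        if self.dt <= 0:
            raise TrackValidationError(f"track {self.cell_id!r}: dt must be > 0")
        if self.t is None:
            self.t = self.frames * float(self.dt)
        else:
            self.t = np.asarray(self.t, dtype=float)
            if not np.allclose(self.t, self.frames * self.dt, atol=1e-6 * max(self.dt, 1.0)):
                raise TrackValidationError(
                    f"track {self.cell_id!r}: t inconsistent with frames * dt"
                )
        if self.myog is None:
            self.myog = np.full(n, "unknown", dtype=object)
        else:
            self.myog = np.asarray(self.myog, dtype=object)
        if self.fibre_contact is None:
            self.fibre_contact = np.full(n, "unknown", dtype=object)
        else:
            self.fibre_contact = np.asarray(self.fibre_contact, dtype=object)
        for name, arr, states in (
            ("myog", self.myog, MYOG_STATES),
            ("fibre_contact", self.fibre_contact, CONTACT_STATES),
        ):
            bad = set(arr) - set(states)
            if bad:
                raise TrackValidationError(
                    f"track {self.cell_id!r}: invalid {name} values {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[TimedPoint]:
        return [
            TimedPoint(int(f), float(t), *map(float, p))
            for f, t, p in zip(self.frames, self.t, self.xyz)
        ]

    @property
    def has_gaps(self) -> bool:
        return len(self) > 1 and bool(np.any(np.diff(self.frames) > 1))

    @property
    def start_t(self) -> float:
        return float(self.t[0])

    @property
    def end_t(self) -> float:
        return float(self.t[-1])

    def with_positions(self, xyz: np.ndarray) -> "Track":
        """Copy of the track with positions replaced (annotations kept)."""
        return replace(
            self,
            xyz=np.asarray(xyz, dtype=float).copy(),
            t=self.t.copy(),
            myog=self.myog.copy(),
            fibre_contact=self.fibre_contact.copy(),
        )

    def segments(self, max_gap: int = DEFAULT_MAX_GAP) -> list["Track"]:
        """Split at gaps of more than ``max_gap`` missing frames.

        Metrics are computed per contiguous segment; a long interruption in
        the observation makes step statistics across it meaningless.
        """
        if len(self) == 1:
            return [self]
        gaps = np.diff(self.frames) - 1
        cut = np.flatnonzero(gaps > max_gap) + 1
        if cut.size == 0:
            return [self]
        out = []
        for i, idx in enumerate(np.split(np.arange(len(self)), cut)):
            out.append(
                Track(
                    cell_id=self.cell_id,
                    dt=self.dt,
                    frames=self.frames[idx],
                    xyz=self.xyz[idx],
                    myog=self.myog[idx],
                    fibre_contact=self.fibre_contact[idx],
                    motility_excluded=self.motility_excluded,
                )
            )
        return out

    def position_at(self, t: float) -> np.ndarray | None:
        """Linearly interpolated position at time ``t`` (min), or None outside."""
        if t < self.t[0] - 1e-9 or t > self.t[-1] + 1e-9:
            return None
        return np.array(
            [np.interp(t, self.t, self.xyz[:, k]) for k in range(3)], dtype=float
        )

    def myog_positive_from(self) -> float | None:
        """Time (min) of first 'positive' observation, treating positivity as
        irreversible (marker onset), or None if never positive."""
        idx = np.flatnonzero(self.myog == "positive")
        if idx.size == 0:
            return None
        return float(self.t[idx[0]])

    def myog_status_at(self, t: float) -> str:
        """MYOG status at time ``t`` under the irreversible-onset convention."""
        onset = self.myog_positive_from()
        if onset is not None:
            return "positive" if t >= onset - 1e-9 else "negative"
        if np.all(self.myog == "unknown"):
            return "unknown"
        return "negative"


@dataclass
class LineageNode:
    """One cell in a lineage: identity, parentage and life span."""

    cell_id: str
    parent_id: str | None = None
    birth_t: float = 0.0
    end_t: float = 0.0
    end_reason: str = "censored"
    fate: str = "unknown"
    generation: int | None = None

    def __post_init__(self) -> None:
        if self.end_reason not in END_REASONS:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: invalid end reason {self.end_reason!r}"
            )
        if self.fate not in MYOG_STATES:
            raise TrackValidationError(
                f"cell {self.cell_id!r}: invalid fate {self.fate!r}"
            )


class LineageTree:
    """Cells linked by parent/daughter relations.

    Invariants enforced on :meth:`validate`: the graph is acyclic, every
    division has exactly two daughters, and a daughter's birth time equals
    the mother's division time.
    """

    def __init__(self, nodes: Sequence[LineageNode] = ()) -> None:
        self.nodes: dict[str, LineageNode] = {}
        self._children: dict[str, list[str]] = {}
        for node in nodes:
            self.add(node)

    def add(self, node: LineageNode) -> None:
        if node.cell_id in self.nodes:
            raise TrackValidationError(f"duplicate cell id {node.cell_id!r}")
        self.nodes[node.cell_id] = node
        self._children.setdefault(node.cell_id, [])
        if node.parent_id is not None:
            self._children.setdefault(node.parent_id, []).append(node.cell_id)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.nodes

    def __iter__(self) -> Iterator[LineageNode]:
        return iter(self.nodes.values())

    def daughters(self, cell_id: str) -> list[str]:
        return list(self._children.get(cell_id, []))

    @property
    def roots(self) -> list[str]:
        return [c for c, n in self.nodes.items() if n.parent_id is None]

    def divisions(self) -> list[str]:
        """Cell ids of mothers that divided (exactly two daughters)."""
        return [c for c in self.nodes if len(self._children.get(c, [])) == 2]

    def generation_of(self, cell_id: str) -> int:
        """1-based generation index (roots are generation 1)."""
        g, node = 1, self.nodes[cell_id]
        seen = {cell_id}
        while node.parent_id is not None:
            if node.parent_id in seen or node.parent_id not in self.nodes:
                raise TrackValidationError(
                    f"cell {cell_id!r}: broken or cyclic ancestry at {node.parent_id!r}"
                )
            seen.add(node.parent_id)
            node = self.nodes[node.parent_id]
            g += 1
        return g

    def validate(self, atol: float = 1e-6) -> None:
        for cid, node in self.nodes.items():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise TrackValidationError(
                    f"cell {cid!r}: unknown parent {node.parent_id!r}"
                )
            kids = self._children.get(cid, [])
            if len(kids) not in (0, 2):
                raise TrackValidationError(
                    f"cell {cid!r}: {len(kids)} daughters (divisions must have 2)"
                )
            if kids:
                if node.end_reason != "division":
                    raise TrackValidationError(
                        f"cell {cid!r}: has daughters but end reason is "
                        f"{node.end_reason!r}"
                    )
                for kid in kids:
                    if abs(self.nodes[kid].birth_t - node.end_t) > atol:
                        raise TrackValidationError(
                            f"cell {kid!r}: birth {self.nodes[kid].birth_t} != "
                            f"mother division {node.end_t}"
                        )
            if node.end_t < node.birth_t - atol:
                raise TrackValidationError(
                    f"cell {cid!r}: ends ({node.end_t}) before birth ({node.birth_t})"
                )
        for cid in self.nodes:  # raises on cycles
            self.generation_of(cid)


@dataclass(frozen=True)
class ShapeDescriptor:
    """Planar shape measurements of one segmented cell."""

    area: float  # μm²
    perimeter: float  # μm
    max_diameter: float  # μm
    min_diameter: float  # μm

    def __post_init__(self) -> None:
        vals = (self.area, self.perimeter, self.max_diameter, self.min_diameter)
        if any(v <= 0 for v in vals):
            raise ValueError(f"shape descriptor fields must be positive, got {vals}")
        if self.max_diameter < self.min_diameter:
            raise ValueError("max_diameter must be >= min_diameter")
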