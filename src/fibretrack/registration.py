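"""Rigid drift correction of tracks from fibre masks or landmark points.

Floating myofibres translate and rotate during imaging, so raw trajectories
mix cell motion with fibre motion.  This module estimates one rigid
transform per frame (frame-to-previous), chains them into frame-to-reference
transforms, and applies the chain to tracks so that positions are expressed
relative to the immobilised fibre.

The point-set estimator is the classic least-squares rigid fit (Kabsch):
given corresponding point sets it returns the rotation/translation pair
minimising the sum of squared residuals, with the reflection excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.measure import inertia_tensor, moments

from .model import Track


class RegistrationError(ValueError):
    """Degenerate input or missing frames in a registration problem."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``p -> R p + t`` in μm, tagged with a frame index."""

    rotation: np.ndarray
    translation: np.ndarray
    frame: int = 0
    translation_only: bool = False  # estimator fell back to centroid shift

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape == (2, 2):  # embed a planar rotation in 3D
            R3 = np.eye(3)
            R3[:2, :2] = R
            R = R3
        if t.shape == (2,):
            t = np.array([t[0], t[1], 0.0])
        if R.shape != (3, 3) or t.shape != (3,):
            raise RegistrationError(
                f"bad transform shapes R{R.shape}, t{t.shape}"
            )
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise RegistrationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise RegistrationError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, frame: int = 0) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame=frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] == 2:
            pts = np.hstack([pts, np.zeros((len(pts), 1))])
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            frame=other.frame,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, frame=self.frame)

    @property
    def angle_deg(self) -> float:
        """In-plane (xy) rotation angle in degrees."""
        return float(
            np.degrees(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))
        )


def estimate_rigid_from_points(
    moving: np.ndarray, fixed: np.ndarray, frame: int = 0
) -> RigidTransform:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Both arguments are (n, 2) or (n, 3) arrays of corresponding points.
    On noise-free rigidly related sets the residual is zero to numerical
    precision.  Raises :class:`RegistrationError` on degenerate
    configurations (too few points, coincident points, or collinear points
    when a 3D rotation is requested).
    """
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if moving.shape != fixed.shape:
        raise RegistrationError(
            f"point sets differ in shape: {moving.shape} vs {fixed.shape}"
        )
    dim = moving.shape[1]
    if dim == 2:
        moving = np.hstack([moving, np.zeros((len(moving), 1))])
        fixed = np.hstack([fixed, np.zeros((len(fixed), 1))])
    elif dim != 3:
        raise RegistrationError(f"points must be 2D or 3D, got {dim}D")
    n_min = 2 if dim == 2 else 3
    if len(moving) < n_min:
        raise RegistrationError(f"need at least {n_min} point pairs, got {len(moving)}")

    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    a, b = moving - mc, fixed - fc
    if np.allclose(a, 0.0, atol=1e-12):
        raise RegistrationError("all moving points coincident")
    # 3D rotation about an arbitrary axis is unconstrained for collinear sets.
    if dim == 3:
        if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
            raise RegistrationError("points are collinear: 3D rotation is degenerate")

    H = a.T @ b  # cross-covariance; Kabsch via SVD with reflection guard
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, fc - R @ mc, frame=frame)


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centroid (x, y), principal-axis angle (rad) and axis ratio of a mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise RegistrationError("empty mask")
    m = moments(mask.astype(float), order=1)
    # skimage uses (row, col); convert to (x, y) = (col, row)
    centroid_rc = np.array([m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]])
    it = inertia_tensor(mask.astype(float))
    evals, evecs = np.linalg.eigh(it)
    # Smallest inertia eigenvalue <-> major axis.
    major_rc = evecs[:, 0]
    angle = float(np.arctan2(major_rc[0], major_rc[1]))  # angle in xy frame
    lam_minor, lam_major = np.sqrt(max(evals[0], 1e-12)), np.sqrt(evals[1])
    ratio = float(lam_major / max(lam_minor, 1e-12))
    centroid_xy = centroid_rc[::-1]
    return centroid_xy, angle, ratio


def estimate_rigid_from_masks(
    mask_t: np.ndarray,
    mask_ref: np.ndarray,
    pixel_size: float = 1.0,
    frame: int = 0,
    min_axis_ratio: float = 1.05,
) -> RigidTransform:
    """Moment-based rigid alignment of a binary fibre mask onto a reference.

    The transform maps the centroid of ``mask_t`` onto the centroid of
    ``mask_ref`` and aligns their principal axes (second central moments).
    The 180° axis ambiguity is resolved by taking the smaller rotation,
    which assumes inter-frame fibre rotation below 90°.  A near-isotropic
    mask (axis ratio < ``min_axis_ratio``) has no usable orientation, so the
    result degrades to a pure centroid shift flagged ``translation_only``.
    """
    c_t, a_t, r_t = _mask_moments(mask_t)
    c_r, a_r, r_r = _mask_moments(mask_ref)
    if min(r_t, r_r) < min_axis_ratio:
        return RigidTransform(
            np.eye(3),
            np.append((c_r - c_t) * pixel_size, 0.0),
            frame=frame,
            translation_only=True,
        )
    dtheta = a_r - a_t
    # axes are directionless: fold into (-90°, 90°]
    while dtheta <= -np.pi / 2:
        dtheta += np.pi
    while dtheta > np.pi / 2:
        dtheta -= np.pi
    c, s = np.cos(dtheta), np.sin(dtheta)
    R = np.array([[c, -s], [s, c]])
    t = c_r * pixel_size - R @ (c_t * pixel_size)
    return RigidTransform(R, t, frame=frame)


def accumulate(transforms: dict[int, RigidTransform]) -> dict[int, RigidTransform]:
    """Chain frame-to-previous transforms into frame-to-reference transforms.

    ``transforms[t]`` must map frame-``t`` coordinates to frame-``t-1``
    coordinates for every frame 1..T with no holes.  Returns ``C`` with
    ``C[0]`` the identity and ``C[t] = C[t-1] ∘ T[t]``, so applying ``C[t]``
    to frame-``t`` data expresses it in the frame-0 referential.
    """
    if not transforms:
        return {0: RigidTransform.identity(0)}
    frames = sorted(transforms)
    expected = list(range(1, max(frames) + 1))
    missing = sorted(set(expected) - set(frames))
    if missing or min(frames) < 1:
        raise RegistrationError(
            f"frame-to-previous transforms must cover frames 1..T; missing {missing}"
        )
    out = {0: RigidTransform.identity(0)}
    for f in expected:
        cumulative = out[f - 1].compose(transforms[f])
        out[f] = RigidTransform(cumulative.rotation, cumulative.translation, frame=f)
    return out


def correct_tracks(
    tracks: list[Track], frame_to_ref: dict[int, RigidTransform]
) -> list[Track]:
    """Map every track point into the static (frame-0) referential.

    Every frame present in any track must have a transform; annotations are
    carried over untouched.
    """
    needed = sorted({int(f) for tr in tracks for f in tr.frames})
    missing = [f for f in needed if f not in frame_to_ref]
    if missing:
        raise RegistrationError(f"no transform for frames {missing}")
    return [track.with_positions(apply_per_frame(frame_to_ref, track.frames, track.xyz))
            for track in tracks]


def apply_per_frame(
    transforms: dict[int, RigidTransform], frames: np.ndarray, xyz: np.ndarray
) -> np.ndarray:
    """Apply ``transforms[frame]`` to each row of ``xyz`` (vectorised)."""
    frames = np.asarray(frames, dtype=int)
    idx = sorted({int(f) for f in frames})
    pos = {f: i for i, f in enumerate(idx)}
    R = np.stack([transforms[f].rotation for f in idx])
    t = np.stack([transforms[f].translation for f in idx])
    sel = np.array([pos[int(f)] for f in frames])
    return np.einsum("nij,nj->ni", R[sel], xyz) + t[sel]


def registration_residuals(
    landmarks: dict[int, np.ndarray], frame_to_ref: dict[int, RigidTransform]
) -> np.ndarray:
    """Per-frame RMS residual (μm) of corrected landmarks vs their frame-0
    positions — the accumulated-drift diagnostic for a registered scene."""
    frames = sorted(landmarks)
    ref = np.atleast_2d(landmarks[frames[0]])
    out = []
    for f in frames:
        corrected = frame_to_ref[f].apply(np.atleast_2d(landmarks[f]))
        out.append(float(np.sqrt(np.mean(np.sum((corrected - ref) ** 2, axis=1)))))
    return np.asarray(out)


def register_landmark_series(
    landmarks: dict[int, np.ndarray],
    residual_threshold: float = 5.0,
) -> tuple[dict[int, RigidTransform], dict]:
    """Frame-to-reference transforms from a labelled landmark series.

    ``landmarks`` maps each frame to an (n, 2|3) array where row ``i`` is
    the same physical landmark in every frame.  Registration is estimated
    iteratively frame-to-previous and chained.  Scenes whose accumulated RMS
    residual exceeds ``residual_threshold`` (μm) are flagged
    ``motility_excluded`` in the returned diagnostics but still registered,
    so they remain usable for lineage analysis.
    """
    frames = sorted(landmarks)
    if frames != list(range(frames[0], frames[0] + len(frames))):
        raise RegistrationError("landmark series has missing frames")
    step = {}
    for prev, cur in zip(frames, frames[1:]):
        step[cur] = estimate_rigid_from_points(
            landmarks[cur], landmarks[prev], frame=cur
        )
    frame_to_ref = accumulate(step)
    residuals = registration_residuals(landmarks, frame_to_ref)
    diagnostics = {
        "max_rms_residual_um": float(residuals.max()),
        "motility_excluded": bool(residuals.max() > residual_threshold),
    }
    return frame_to_ref, diagnostics


# ---------------------------------------------------------------------------
# Transforms CSV
# ---------------------------------------------------------------------------

_TRANSFORM_COLUMNS = (
    "frame",
    "r11", "r12", "r13",
    "r21", "r22", "r23",
    "r31", "r32", "r33",
    "tx", "ty", "tz",
)


def write_transforms_csv(
    transforms: dict[int, RigidTransform], path: str | Path
) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TRANSFORM_COLUMNS)
        for f in sorted(transforms):
            tr = transforms[f]
            writer.writerow(
                [f]
                + ["%.12g" % v for v in tr.rotation.ravel()]
                + ["%.12g" % v for v in tr.translation]
            )
    return path


def read_transforms_csv(path: str | Path) -> dict[int, RigidTransform]:
    path = Path(path)
    out = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _TRANSFORM_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise RegistrationError(f"{path}: missing columns {missing}")
        for row in reader:
            f = int(row["frame"])
            R = np.array(
                [float(row[f"r{i}{j}"]) for i in (1, 2, 3) for j in (1, 2, 3)]
            ).reshape(3, 3)
            t = np.array([float(row["tx"]), float(row["ty"]), float(row["tz"])])
            out[f] = RigidTransform(R, t, frame=f)
    return out
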