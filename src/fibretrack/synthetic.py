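"""Synthetic scenes with the statistical structure the pipeline assumes.

The generator emulates three layers of the ex vivo myofibre imaging data:

* rigid fibre drift — a per-frame random walk in rotation (about the field
  centre) and translation, applied to ground-truth tracks to produce the
  "observed" tracks, with landmark points and optional binary fibre masks
  for the registration stage;
* a two-population motility mixture — mobile cells follow a persistent
  random walk with lognormal step speeds, static cells jitter around an
  anchor point; and
* stochastic lineages — founders activate (first division) after a normal
  delay, then divide with generation-dependent cycle times; each division
  draws a mode (ACD / SCDd / SCDp) from a multinomial and an orientation
  independently, daughter MYOG fates follow the mode, marker expression
  appears with a delay after birth, and a small fraction of MYOG-positive
  cells divide once more.

Presets named ``"wt"`` and ``"mdx"`` carry calibrations to the measured
values for healthy and dystrophic muscle stem cells.  Full ground truth
(static-referential tracks, true transforms, true modes and fates) is kept
so every pipeline stage can be scored against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import LineageNode, LineageTree, Track
from .registration import RigidTransform, write_transforms_csv
from . import io as track_io


class PresetError(ValueError):
    """A simulation preset violates a parameter constraint."""


@dataclass(frozen=True)
class SimulationPreset:
    """Full generative parameter set for one genotype/condition.

    Speeds are μm/h at the interface (converted internally to μm/min),
    times are hours, angles degrees.  ``mode_probs`` is (ACD, SCDd, SCDp).
    """

    name: str = "wt"
    dt_min: float = 10.0
    movie_h: float = 72.0
    field_um: tuple[float, float] = (650.0, 120.0)

    # fibre motion: per-frame random-walk increments
    fibre_rot_sd_deg: float = 0.3
    fibre_trans_sd_um: float = 0.8
    n_landmarks: int = 8

    # motility mixture
    f_mobile: float = 0.52
    mobile_speed_mean_um_h: float = 46.4
    mobile_speed_sigma_log: float = 0.25
    cell_speed_sigma_log: float = 0.15
    static_step_speed_um_min: float = 0.1
    persistence_turn_sd_deg: float = 30.0

    # post-mitotic dispersal of sister cells
    dispersal_min: float = 60.0
    dispersal_opposite_prob: float = 0.975
    dispersal_heading_sd_deg: float = 15.0
    dispersal_speed_um_min: float = 0.6

    # cell-cycle timing
    activation_mean_h: float = 47.3
    activation_sd_h: float = 10.0
    cycle_mean_h: float = 8.5
    cycle_sd_h: float = 2.0
    cycle_generation_multiplier: float = 1.0
    min_cycle_h: float = 1.0

    # division modes and fates; mode_probs are the target fractions over all
    # classified divisions, including the SCDd redivisions of MYOG-positive
    # cells (redivision_division_share of all divisions, a calibration), so
    # the multinomial actually drawn for MYOG-negative mothers is deflated
    # accordingly (see mode_draw_probs).
    mode_probs: tuple[float, float, float] = (0.129, 0.325, 0.546)
    redivision_division_share: float = 0.048
    orientation_probs: tuple[float, float, float] = (0.680, 0.189, 0.131)
    myog_onset_mean_h: float = 9.0
    myog_onset_sd_h: float = 2.0
    redivision_prob: float = 0.091
    #: endpoint differentiation index the preset is calibrated to reproduce
    calibrated_diff_index: float = 0.38

    def __post_init__(self) -> None:
        probs = (
            self.f_mobile,
            self.dispersal_opposite_prob,
            self.redivision_prob,
            self.calibrated_diff_index,
            *self.mode_probs,
            *self.orientation_probs,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise PresetError(f"preset {self.name!r}: probabilities must be in [0, 1]")
        for probs3, what in ((self.mode_probs, "mode"), (self.orientation_probs, "orientation")):
            if abs(sum(probs3) - 1.0) > 1e-9:
                raise PresetError(
                    f"preset {self.name!r}: {what} probabilities sum to {sum(probs3)}"
                )
        sds = (
            self.fibre_rot_sd_deg,
            self.fibre_trans_sd_um,
            self.mobile_speed_sigma_log,
            self.cell_speed_sigma_log,
            self.persistence_turn_sd_deg,
            self.dispersal_heading_sd_deg,
            self.activation_sd_h,
            self.cycle_sd_h,
            self.myog_onset_sd_h,
        )
        if any(s < 0 for s in sds):
            raise PresetError(f"preset {self.name!r}: SDs must be >= 0")
        if self.dt_min <= 0 or self.movie_h <= 0:
            raise PresetError(f"preset {self.name!r}: dt and movie length must be > 0")

    def replace(self, **overrides) -> "SimulationPreset":
        return dataclasses.replace(self, **overrides)

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_h * 60.0 / self.dt_min)) + 1

    def cycle_mean_for_generation(self, generation: int) -> float:
        """Mean cycle length (h) of a generation-``g`` cell (g >= 2); the
        multiplier compounds per generation (1.0 in wild type)."""
        return self.cycle_mean_h * self.cycle_generation_multiplier ** (generation - 1)

    @property
    def mode_draw_probs(self) -> tuple[float, float, float]:
        """(ACD, SCDd, SCDp) multinomial drawn at a MYOG-negative mother's
        division.  Redivisions of positive cells are always SCDd and make up
        ``redivision_division_share`` of all divisions, so the drawn SCDd
        probability is deflated to keep the totals at ``mode_probs``."""
        r = self.redivision_division_share
        acd, scdd, scdp = self.mode_probs
        if scdd - r < 0:
            raise PresetError(
                f"preset {self.name!r}: redivision share {r} exceeds SCDd fraction"
            )
        return (acd / (1.0 - r), (scdd - r) / (1.0 - r), scdp / (1.0 - r))


#: Division-mode probabilities are (ACD, SCDd, SCDp), renormalised where the
#: printed percentages sum to 99.9%.  The mdx cycle multiplier and the
#: dispersal/persistence parameters are generator calibrations, not
#: measured values (see the methods note).
_PRESETS = {
    "wt": SimulationPreset(name="wt"),
    "mdx": SimulationPreset(
        name="mdx",
        f_mobile=0.19,
        mobile_speed_mean_um_h=36.4,
        dispersal_opposite_prob=0.80,
        activation_mean_h=40.4,
        cycle_generation_multiplier=1.2,
        mode_probs=(0.144, 0.577, 0.279),
        redivision_division_share=0.08,
        calibrated_diff_index=0.76,
    ),
}


def preset(name: str, **overrides) -> SimulationPreset:
    """Look up a named preset (``"wt"`` or ``"mdx"``), with field overrides."""
    try:
        base = _PRESETS[name.lower()]
    except KeyError:
        raise PresetError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return base.replace(**overrides) if overrides else base


@dataclass
class SyntheticScene:
    """One simulated movie with complete ground truth."""

    preset: SimulationPreset
    seed: int
    truth_tracks: list[Track]
    observed_tracks: list[Track]
    lineage: LineageTree
    #: frame-to-reference fibre transforms F_t: static coords -> observed
    #: frame-t coords (the correction the pipeline must recover is F_t^-1)
    true_transforms: dict[int, RigidTransform]
    #: per-frame observed landmark coordinates, shape (n_landmarks, 3)
    landmarks: dict[int, np.ndarray]
    #: per-cell ground truth: mobility class, fate, division mode
    truth: dict[str, dict]


# ---------------------------------------------------------------------------
# fibre motion
# ---------------------------------------------------------------------------


def simulate_fibre_motion(
    preset: SimulationPreset, n_frames: int, seed: int | np.random.Generator
) -> dict[int, RigidTransform]:
    """Cumulative random-walk rigid fibre motion, one transform per frame.

    ``F_0`` is the identity; per frame the fibre rotates about the field
    centre by a normal increment (SD ``fibre_rot_sd_deg``) and translates by
    a normal increment per axis (SD ``fibre_trans_sd_um``).  The returned
    ``F_t`` maps static-referential coordinates to observed frame-``t``
    coordinates.
    """
    if n_frames < 1:
        raise PresetError("n_frames must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centre = np.array([preset.field_um[0] / 2.0, preset.field_um[1] / 2.0, 0.0])
    out = {0: RigidTransform.identity(0)}
    angle = 0.0
    shift = np.zeros(2)
    for f in range(1, n_frames):
        angle += rng.normal(0.0, np.radians(preset.fibre_rot_sd_deg))
        shift = shift + rng.normal(0.0, preset.fibre_trans_sd_um, size=2)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = centre - R @ centre + np.array([shift[0], shift[1], 0.0])
        out[f] = RigidTransform(R, t, frame=f)
    return out


def _landmark_series(
    preset: SimulationPreset,
    transforms: dict[int, RigidTransform],
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Observed positions of fixed fibre landmarks under the fibre motion."""
    w, h = preset.field_um
    static = np.column_stack(
        [
            rng.uniform(0.1 * w, 0.9 * w, size=preset.n_landmarks),
            rng.uniform(0.1 * h, 0.9 * h, size=preset.n_landmarks),
            np.zeros(preset.n_landmarks),
        ]
    )
    return {f: transforms[f].apply(static) for f in sorted(transforms)}


def fibre_masks(
    preset: SimulationPreset,
    transforms: dict[int, RigidTransform],
    pixel_size_um: float = 2.0,
    semi_axes_um: tuple[float, float] = (280.0, 40.0),
) -> dict[int, np.ndarray]:
    """Binary elliptical fibre masks consistent with the fibre motion.

    A pixel is inside the frame-``t`` mask when its μm coordinate, mapped
    back to the static referential with ``F_t^{-1}``, lies in the ellipse
    centred on the field.  Purely geometric: no intensity synthesis.
    """
    w, h = preset.field_um
    shape = (int(np.ceil(h / pixel_size_um)), int(np.ceil(w / pixel_size_um)))
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack(
        [
            (cols.ravel() + 0.5) * pixel_size_um,
            (rows.ravel() + 0.5) * pixel_size_um,
            np.zeros(rows.size),
        ]
    )
    centre = np.array([w / 2.0, h / 2.0, 0.0])
    a, b = semi_axes_um
    out = {}
    for f in sorted(transforms):
        back = transforms[f].inverse().apply(pts) - centre
        inside = (back[:, 0] / a) ** 2 + (back[:, 1] / b) ** 2 <= 1.0
        out[f] = inside.reshape(shape)
    return out


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------


def _mobile_steps(
    preset: SimulationPreset,
    n_steps: int,
    speed_factor: float,
    rng: np.random.Generator,
    heading: float | None = None,
    fixed_heading_until: int = 0,
) -> np.ndarray:
    """Persistent-random-walk displacement steps (n_steps, 3) in μm."""
    mean_um_min = preset.mobile_speed_mean_um_h / 60.0 * speed_factor
    sigma = preset.mobile_speed_sigma_log
    mu = np.log(mean_um_min) - 0.5 * sigma**2
    speeds = rng.lognormal(mu, sigma, size=n_steps)
    theta0 = rng.uniform(0.0, 2.0 * np.pi) if heading is None else heading
    turn_sd = np.full(n_steps, np.radians(preset.persistence_turn_sd_deg))
    turn_sd[:fixed_heading_until] = np.radians(5.0)
    theta = theta0 + np.cumsum(rng.normal(0.0, 1.0, size=n_steps) * turn_sd)
    d = speeds * preset.dt_min
    return np.column_stack([d * np.cos(theta), d * np.sin(theta), np.zeros(n_steps)])


def _static_positions(
    preset: SimulationPreset, anchor: np.ndarray, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian jitter around an anchor; the jitter SD is set so the mean
    apparent step speed equals ``static_step_speed_um_min``."""
    sd = preset.static_step_speed_um_min * preset.dt_min / np.sqrt(np.pi)
    jitter = rng.normal(0.0, sd, size=(n_points, 2))
    out = np.tile(anchor, (n_points, 1))
    out[:, :2] += jitter
    return out


def _dispersal_steps(
    preset: SimulationPreset, n_steps: int, heading: float, rng: np.random.Generator
) -> np.ndarray:
    """Ballistic post-mitotic separation steps along a fixed heading."""
    d = preset.dispersal_speed_um_min * preset.dt_min * rng.lognormal(-0.02, 0.2, n_steps)
    theta = heading + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, np.radians(5.0), size=n_steps - 1))]
    ) if n_steps else np.array([])
    return np.column_stack([d * np.cos(theta), d * np.sin(theta), np.zeros(n_steps)])


def simulate_tracks(
    preset: SimulationPreset, n_cells: int, seed: int
) -> SyntheticScene:
    """Simulate a division-free scene of the two-population speed mixture.

    Each cell is mobile with probability ``f_mobile``.  Mobile cells follow
    a persistent random walk with lognormal step speeds (a per-cell
    lognormal speed factor with unit mean adds cell-level heterogeneity);
    static cells jitter around their anchor.  Observed tracks are the
    ground-truth tracks with the fibre motion applied.
    """
    if n_cells <= 0:
        raise PresetError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    n_frames = preset.n_frames
    transforms = simulate_fibre_motion(preset, n_frames, rng)
    landmarks = _landmark_series(preset, transforms, rng)
    w, h = preset.field_um

    truth_tracks, observed_tracks, truth = [], [], {}
    lineage = LineageTree()
    frames = np.arange(n_frames)
    for k in range(n_cells):
        cid = f"cell{k:04d}"
        start = np.array([rng.uniform(0.05 * w, 0.95 * w), rng.uniform(0.2 * h, 0.8 * h), 0.0])
        mobile = rng.random() < preset.f_mobile
        factor = rng.lognormal(
            -0.5 * preset.cell_speed_sigma_log**2, preset.cell_speed_sigma_log
        )
        if mobile:
            steps = _mobile_steps(preset, n_frames - 1, factor, rng)
            xyz = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        else:
            xyz = _static_positions(preset, start, n_frames, rng)
        track = Track(cell_id=cid, dt=preset.dt_min, frames=frames, xyz=xyz)
        truth_tracks.append(track)
        observed_tracks.append(_apply_motion(track, transforms))
        truth[cid] = {"mobile": bool(mobile), "speed_factor": float(factor)}
        lineage.add(
            LineageNode(
                cell_id=cid,
                birth_t=0.0,
                end_t=track.end_t,
                end_reason="censored",
            )
        )
    return SyntheticScene(
        preset=preset,
        seed=seed,
        truth_tracks=truth_tracks,
        observed_tracks=observed_tracks,
        lineage=lineage,
        true_transforms=transforms,
        landmarks=landmarks,
        truth=truth,
    )


def _apply_motion(track: Track, transforms: dict[int, RigidTransform]) -> Track:
    from .registration import apply_per_frame

    return track.with_positions(apply_per_frame(transforms, track.frames, track.xyz))


# ---------------------------------------------------------------------------
# lineages
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    return float(max(rng.normal(mean, sd), lower))


def simulate_lineages(
    preset: SimulationPreset, n_founders: int, seed: int
) -> SyntheticScene:
    """Simulate dividing lineages with modes, orientations and MYOG fates.

    Founders divide after a normal activation delay, later generations after
    generation-dependent cycle draws.  Each division draws a mode from the
    (ACD, SCDd, SCDp) multinomial and an orientation independently; daughter
    fates follow the mode; fated-positive cells express the marker after a
    normal onset delay and divide once more with probability
    ``redivision_prob`` (such divisions are SCDd).  Daughters disperse from
    the mitosis site in near-opposite directions with probability
    ``dispersal_opposite_prob``, then resume their drawn mobility class.
    """
    if n_founders <= 0:
        raise PresetError("n_founders must be positive")
    if preset.movie_h < preset.activation_mean_h * 0.5:
        raise PresetError("movie shorter than half the mean activation time")
    rng = np.random.default_rng(seed)
    n_frames = preset.n_frames
    movie_end_min = (n_frames - 1) * preset.dt_min
    transforms = simulate_fibre_motion(preset, n_frames, rng)
    landmarks = _landmark_series(preset, transforms, rng)
    w, h = preset.field_um

    lineage = LineageTree()
    truth_tracks: list[Track] = []
    truth: dict[str, dict] = {}
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"cell{counter[0]:05d}"

    # (cell_id, parent_id, birth_min, fated_positive, inherits_marker,
    #  start_pos, dispersal_heading or None, generation)
    queue = []
    for _ in range(n_founders):
        start = np.array(
            [rng.uniform(0.05 * w, 0.95 * w), rng.uniform(0.2 * h, 0.8 * h), 0.0]
        )
        queue.append((next_id(), None, 0.0, False, False, start, None, 1))

    while queue:
        cid, pid, birth, fated_pos, inherits, start, disp_heading, gen = queue.pop(0)
        mobile = rng.random() < preset.f_mobile
        factor = rng.lognormal(
            -0.5 * preset.cell_speed_sigma_log**2, preset.cell_speed_sigma_log
        )
        onset_min = None
        if fated_pos:
            # a daughter of an already-expressing mother is born with the
            # marker; a newly committed cell expresses after the onset delay
            if inherits:
                onset_min = birth
            else:
                onset_min = birth + 60.0 * _truncated_normal(
                    rng, preset.myog_onset_mean_h, preset.myog_onset_sd_h, 0.5
                )

        # --- life span -----------------------------------------------------
        if gen == 1:
            cycle_h = _truncated_normal(
                rng, preset.activation_mean_h, preset.activation_sd_h, preset.min_cycle_h
            )
        else:
            mean = preset.cycle_mean_for_generation(gen)
            sd = preset.cycle_sd_h * mean / preset.cycle_mean_h  # constant CV
            cycle_h = _truncated_normal(rng, mean, sd, preset.min_cycle_h)
        will_divide = not fated_pos or rng.random() < preset.redivision_prob
        div_min = birth + cycle_h * 60.0
        divides = will_divide and div_min <= movie_end_min
        end_min = div_min if divides else movie_end_min

        # --- trajectory ----------------------------------------------------
        f0 = int(np.ceil(round(birth / preset.dt_min, 9)))
        f1 = int(np.floor(round(end_min / preset.dt_min, 9)))
        f1 = min(f1, n_frames - 1)
        orientation = None
        if f1 >= f0:
            frames = np.arange(f0, f1 + 1)
            n_pts = len(frames)
            if disp_heading is not None:
                n_disp = min(n_pts - 1, int(round(preset.dispersal_min / preset.dt_min)))
                n_disp = max(n_disp, 0)
            else:
                n_disp = 0
            if n_pts >= 2:
                parts = []
                if n_disp:
                    parts.append(_dispersal_steps(preset, n_disp, disp_heading, rng))
                n_rest = n_pts - 1 - n_disp
                if n_rest > 0:
                    if mobile:
                        parts.append(
                            _mobile_steps(preset, n_rest, factor, rng, heading=disp_heading)
                        )
                    else:
                        sd = preset.static_step_speed_um_min * preset.dt_min / np.sqrt(np.pi)
                        anchor_jitter = rng.normal(0.0, sd, size=(n_rest, 2))
                        steps = np.zeros((n_rest, 3))
                        steps[:, :2] = np.diff(
                            np.vstack([np.zeros(2), anchor_jitter]), axis=0
                        )
                        parts.append(steps)
                steps = np.vstack(parts)
                xyz = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            else:
                xyz = start[None, :]
            myog = np.array(
                [
                    "positive"
                    if onset_min is not None and t >= onset_min
                    else "negative"
                    for t in frames * preset.dt_min
                ],
                dtype=object,
            )
            track = Track(
                cell_id=cid, dt=preset.dt_min, frames=frames, xyz=xyz, myog=myog
            )
            truth_tracks.append(track)
            final_pos = xyz[-1]
        else:
            track = None
            final_pos = start

        # --- division ------------------------------------------------------
        if divides:
            mode = ("ACD", "SCDd", "SCDp")[
                rng.choice(3, p=preset.mode_draw_probs) if not fated_pos else 1
            ]
            orientation = ("planar", "perpendicular", "undetermined")[
                rng.choice(3, p=preset.orientation_probs)
            ]
            if mode == "SCDp":
                d_fates = (False, False)
            elif mode == "SCDd":
                d_fates = (True, True)
            else:
                d_fates = (True, False) if rng.random() < 0.5 else (False, True)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            if rng.random() < preset.dispersal_opposite_prob:
                phi_b = phi + np.pi + rng.normal(0.0, np.radians(preset.dispersal_heading_sd_deg))
            else:
                phi_b = phi + rng.normal(0.0, np.radians(preset.dispersal_heading_sd_deg))
            mother_expressing = onset_min is not None and onset_min <= end_min
            daughters = []
            for d_fate, d_phi in zip(d_fates, (phi, phi_b)):
                daughters.append(
                    (
                        next_id(),
                        cid,
                        end_min,
                        d_fate,
                        d_fate and mother_expressing,
                        final_pos.copy(),
                        d_phi,
                        gen + 1,
                    )
                )
            queue.extend(daughters)

        lineage.add(
            LineageNode(
                cell_id=cid,
                parent_id=pid,
                birth_t=birth,
                end_t=end_min,
                end_reason="division" if divides else "censored",
                fate="positive" if fated_pos else "negative",
                generation=gen,
            )
        )
        truth[cid] = {
            "mobile": bool(mobile),
            "fated_positive": bool(fated_pos),
            "generation": gen,
            "division_mode": mode if divides else None,
            "orientation": orientation if divides else None,
        }

    observed_tracks = [_apply_motion(t, transforms) for t in truth_tracks]
    lineage.validate()
    scene = SyntheticScene(
        preset=preset,
        seed=seed,
        truth_tracks=truth_tracks,
        observed_tracks=observed_tracks,
        lineage=lineage,
        true_transforms=transforms,
        landmarks=landmarks,
        truth=truth,
    )
    _apply_orientation_flags(scene, rng)
    return scene


def _apply_orientation_flags(scene: SyntheticScene, rng: np.random.Generator) -> None:
    """Record each division's orientation as the daughters' fibre-contact
    flags in the first two post-mitotic frames (planar: both in contact;
    perpendicular: one detached; undetermined: one unknown)."""
    truth_by_id = {t.cell_id: t for t in scene.truth_tracks}
    obs_by_id = {t.cell_id: t for t in scene.observed_tracks}
    for mother in scene.lineage.divisions():
        orientation = scene.truth[mother].get("orientation")
        if orientation is None:
            continue
        kids = scene.lineage.daughters(mother)
        if orientation == "planar":
            flags = ["contact", "contact"]
        elif orientation == "perpendicular":
            flags = ["contact", "no_contact"]
        else:
            flags = ["contact", "unknown"]
        rng.shuffle(flags)
        for kid, flag in zip(kids, flags):
            for by_id in (truth_by_id, obs_by_id):
                track = by_id.get(kid)
                if track is not None:
                    track.fibre_contact[: min(2, len(track))] = flag


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_scene(scene: SyntheticScene, directory: str | Path) -> dict[str, Path]:
    """Write a scene to disk in the formats the pipeline reads.

    Writes the observed tracks as CSV and XML, landmark coordinates, the
    true per-frame transforms, the ground-truth static-referential tracks,
    and a YAML sidecar with the preset and the per-cell truth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "observed_csv": directory / "observed_tracks.csv",
        "observed_xml": directory / "observed_tracks.xml",
        "truth_csv": directory / "truth_tracks.csv",
        "transforms_csv": directory / "true_transforms.csv",
        "landmarks_csv": directory / "landmarks.csv",
        "sidecar_yaml": directory / "scene.yaml",
    }
    track_io.write_tracks_csv(scene.observed_tracks, scene.lineage, paths["observed_csv"])
    track_io.write_tracks_xml(scene.observed_tracks, scene.lineage, paths["observed_xml"])
    track_io.write_tracks_csv(scene.truth_tracks, scene.lineage, paths["truth_csv"])
    write_transforms_csv(scene.true_transforms, paths["transforms_csv"])
    with paths["landmarks_csv"].open("w") as fh:
        fh.write("frame,landmark,x_um,y_um,z_um\n")
        for f in sorted(scene.landmarks):
            for i, p in enumerate(scene.landmarks[f]):
                fh.write(
                    f"{f},{i}," + ",".join("%.10g" % v for v in p) + "\n"
                )
    mode_counts: dict[str, int] = {}
    for rec in scene.truth.values():
        mode = rec.get("division_mode")
        if mode:
            mode_counts[mode] = mode_counts.get(mode, 0) + 1
    sidecar = {
        "preset": dataclasses.asdict(scene.preset),
        "seed": scene.seed,
        "n_cells": len(scene.truth),
        "division_mode_counts": mode_counts,
        "cells": scene.truth,
    }
    with paths["sidecar_yaml"].open("w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return paths


def read_landmarks_csv(path: str | Path) -> dict[int, np.ndarray]:
    """Read the landmark series written by :func:`export_scene`."""
    import csv as _csv

    per_frame: dict[int, list] = {}
    with Path(path).open(newline="") as fh:
        for row in _csv.DictReader(fh):
            per_frame.setdefault(int(row["frame"]), []).append(
                (int(row["landmark"]), float(row["x_um"]), float(row["y_um"]), float(row["z_um"]))
            )
    out = {}
    for f, rows in per_frame.items():
        rows.sort()
        out[f] = np.array([[x, y, z] for _, x, y, z in rows])
    return out
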