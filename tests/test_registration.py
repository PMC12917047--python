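"""Rigid estimation, composition and track correction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fibretrack as ft
from fibretrack.registration import (
    RegistrationError,
    RigidTransform,
    read_transforms_csv,
    registration_residuals,
    write_transforms_csv,
)
from fibretrack.synthetic import fibre_masks

from conftest import make_track


def rot2(deg):
    th = np.radians(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestPointRegistration:
    def test_identity_on_identical_sets(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 1.0]])
        tr = ft.estimate_rigid_from_points(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0.0, atol=1e-12)

    def test_recovers_square_rotation_and_shift(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        target = square @ rot2(90).T + [5, 0]
        tr = ft.estimate_rigid_from_points(square, target)
        assert tr.angle_deg == pytest.approx(90.0, abs=1e-9)
        rms = np.sqrt(np.mean(np.sum((tr.apply(square)[:, :2] - target) ** 2, axis=1)))
        assert rms < 1e-9

    def test_matches_scipy_kabsch(self):
        """Independent cross-check of the rotation against scipy's
        align_vectors on centred point sets."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3))
        R_true = Rotation.random(rng=1).as_matrix()
        b = a @ R_true.T + [3.0, -1.0, 2.0]
        tr = ft.estimate_rigid_from_points(a, b)
        R_scipy, _ = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert np.allclose(tr.rotation, R_scipy.as_matrix(), atol=1e-8)

    def test_noise_residual_bounded(self):
        """RMS residual of the least-squares fit stays below 2 sigma for
        isotropic Gaussian landmark noise, pooled over 100 seeds."""
        base = np.array([[0, 0], [10, 0], [10, 5], [0, 5], [5, 2.0]])
        sigma = 0.5
        sq = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            moved = base @ rot2(17).T + [4, -2] + rng.normal(0, sigma, base.shape)
            tr = ft.estimate_rigid_from_points(base, moved)
            res = tr.apply(base)[:, :2] - moved
            sq.append(np.sum(res**2, axis=1))
        assert np.sqrt(np.mean(sq)) <= 2 * sigma

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(RegistrationError, match="coincident"):
            ft.estimate_rigid_from_points(np.zeros((3, 2)), np.zeros((3, 2)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(RegistrationError, match="collinear"):
            ft.estimate_rigid_from_points(line, line + 1.0)
        with pytest.raises(RegistrationError, match="at least"):
            ft.estimate_rigid_from_points(np.array([[0.0, 0]]), np.array([[1.0, 0]]))


class TestMaskRegistration:
    def test_identity_on_identical_masks(self):
        p = ft.preset("wt")
        masks = fibre_masks(p, {0: RigidTransform.identity(0)})
        tr = ft.estimate_rigid_from_masks(masks[0], masks[0])
        assert abs(tr.angle_deg) < 1e-9
        assert np.allclose(tr.translation, 0.0, atol=1e-9)

    def test_pure_translation_recovered(self):
        p = ft.preset("wt")
        shift = RigidTransform(np.eye(3), [10.0, -4.0, 0.0])
        masks = fibre_masks(p, {0: RigidTransform.identity(0), 1: shift}, pixel_size_um=1.0)
        tr = ft.estimate_rigid_from_masks(masks[1], masks[0], pixel_size=1.0)
        # mapping frame-1 onto frame-0 inverts the applied shift
        assert np.allclose(tr.translation[:2], [-10.0, 4.0], atol=0.5)
        assert abs(tr.angle_deg) < 0.5

    def test_rotation_recovered_within_half_degree(self):
        p = ft.preset("wt")
        centre = np.array([p.field_um[0] / 2, p.field_um[1] / 2, 0.0])
        R = np.eye(3)
        R[:2, :2] = rot2(20)
        rot = RigidTransform(R, centre - R @ centre)
        masks = fibre_masks(
            p,
            {0: RigidTransform.identity(0), 1: rot},
            pixel_size_um=1.0,
            semi_axes_um=(45.0, 12.0),  # fits the field at any rotation
        )
        tr = ft.estimate_rigid_from_masks(masks[1], masks[0], pixel_size=1.0)
        assert tr.angle_deg == pytest.approx(-20.0, abs=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(RegistrationError, match="empty"):
            ft.estimate_rigid_from_masks(np.zeros((10, 10), bool), np.ones((10, 10), bool))

    def test_isotropic_mask_falls_back_to_translation(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (xx - 32) ** 2 + (yy - 32) ** 2 < 15**2
        disc2 = (xx - 40) ** 2 + (yy - 30) ** 2 < 15**2
        tr = ft.estimate_rigid_from_masks(disc2, disc)
        assert tr.translation_only
        assert np.allclose(tr.rotation, np.eye(3))


class TestAccumulateAndCorrect:
    def test_identity_chain(self):
        chain = {f: RigidTransform.identity(f) for f in range(1, 5)}
        cum = ft.accumulate(chain)
        for f, tr in cum.items():
            assert np.allclose(tr.rotation, np.eye(3))
            assert np.allclose(tr.translation, 0.0)

    def test_rotations_compose(self):
        R = np.eye(3)
        R[:2, :2] = rot2(10)
        chain = {f: RigidTransform(R, np.zeros(3), frame=f) for f in (1, 2)}
        cum = ft.accumulate(chain)
        assert cum[2].angle_deg == pytest.approx(20.0)

    def test_missing_frame_reported(self):
        chain = {1: RigidTransform.identity(1), 3: RigidTransform.identity(3)}
        with pytest.raises(RegistrationError, match="2"):
            ft.accumulate(chain)

    def test_transform_roundtrip_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            tr = RigidTransform(R, rng.normal(size=3))
            pts = rng.normal(size=(7, 3))
            assert np.abs(tr.inverse().apply(tr.apply(pts)) - pts).max() < 1e-9

    def test_comoving_point_restored(self):
        """A point rigidly attached to the fibre maps back to its frame-0
        position after chaining the estimated frame-to-previous transforms."""
        p = ft.preset("wt", movie_h=3.0, fibre_rot_sd_deg=1.0, fibre_trans_sd_um=2.0)
        scene = ft.simulate_tracks(p, 1, seed=8)
        step = {}
        for f in range(1, p.n_frames):
            step[f] = ft.estimate_rigid_from_points(
                scene.landmarks[f], scene.landmarks[f - 1], frame=f
            )
        cum = ft.accumulate(step)
        point0 = scene.landmarks[0][3]
        for f in range(p.n_frames):
            restored = cum[f].apply(scene.landmarks[f][3])
            assert np.linalg.norm(restored - point0) < 1e-6

    def test_identity_correction_leaves_tracks(self):
        tr = make_track([(0, 0), (1, 1), (2, 0)])
        cum = {f: RigidTransform.identity(f) for f in range(3)}
        out = ft.correct_tracks([tr], cum)
        assert np.allclose(out[0].xyz, tr.xyz)

    def test_missing_track_frame_reported(self):
        tr = make_track([(0, 0), (1, 1), (2, 0)])
        with pytest.raises(RegistrationError, match="2"):
            ft.correct_tracks([tr], {0: RigidTransform.identity(0), 1: RigidTransform.identity(1)})

    def test_cell_attached_to_fibre_becomes_stationary(self):
        p = ft.preset("wt", movie_h=2.0, fibre_rot_sd_deg=1.0, fibre_trans_sd_um=2.0)
        transforms = ft.simulate_fibre_motion(p, p.n_frames, 3)
        anchor = np.array([100.0, 60.0, 0.0])
        frames = np.arange(p.n_frames)
        observed = np.vstack([transforms[f].apply(anchor) for f in frames])
        track = ft.Track("glued", p.dt_min, frames, observed)
        cum = {f: transforms[f].inverse() for f in frames}
        corrected = ft.correct_tracks([track], cum)[0]
        net = np.linalg.norm(corrected.xyz[-1] - corrected.xyz[0])
        assert net < 1e-6

    def test_correction_matches_ground_truth(self):
        scene = ft.simulate_tracks(ft.preset("wt", movie_h=4.0), 10, seed=2)
        cum, diag = ft.register_landmark_series(scene.landmarks)
        corrected = ft.correct_tracks(scene.observed_tracks, cum)
        for c, t in zip(corrected, scene.truth_tracks):
            assert np.abs(c.xyz - t.xyz).max() < 1e-3
        assert not diag["motility_excluded"]

    def test_residual_flagging(self):
        """Landmark series with non-rigid scrambling exceeds the residual
        threshold and is flagged motility-excluded."""
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, size=(6, 3))
        base[:, 2] = 0
        series = {f: base + rng.normal(0, 8.0, size=base.shape) for f in range(5)}
        for f in series:
            series[f][:, 2] = 0
        cum, diag = ft.register_landmark_series(series, residual_threshold=5.0)
        assert diag["motility_excluded"]
        res = registration_residuals(series, cum)
        assert res.max() > 5.0

    def test_transforms_csv_roundtrip(self, tmp_path):
        p = ft.preset("wt", movie_h=1.0)
        transforms = ft.simulate_fibre_motion(p, 5, 1)
        path = write_transforms_csv(transforms, tmp_path / "t.csv")
        back = read_transforms_csv(path)
        for f in transforms:
            assert np.abs(back[f].rotation - transforms[f].rotation).max() < 1e-10
            assert np.abs(back[f].translation - transforms[f].translation).max() < 1e-9
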