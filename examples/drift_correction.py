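"""Removing fibre drift from observed tracks.

Simulates a short scene in which the fibre rotates and translates between
frames, registers each frame to the previous one from the landmark points,
chains the transforms, and corrects the observed tracks back into the
static referential.  The apparent motion of a static cell disappears after
correction.
"""

import numpy as np

import fibretrack as ft

preset = ft.preset("wt", movie_h=6.0, fibre_rot_sd_deg=1.0, fibre_trans_sd_um=2.0)
scene = ft.simulate_tracks(preset, n_cells=30, seed=11)

frame_to_ref, diagnostics = ft.register_landmark_series(scene.landmarks)
corrected = ft.correct_tracks(scene.observed_tracks, frame_to_ref)

static_ids = [cid for cid, rec in scene.truth.items() if not rec["mobile"]]
raw = {t.cell_id: t for t in scene.observed_tracks}
fixed = {t.cell_id: t for t in corrected}

before = np.mean([ft.path_summary(raw[c]).net_distance for c in static_ids])
after = np.mean([ft.path_summary(fixed[c]).net_distance for c in static_ids])
err = max(
    np.abs(c.xyz - t.xyz).max() for c, t in zip(corrected, scene.truth_tracks)
)

print(f"static cells:                      {len(static_ids)}")
print(f"mean net distance before:          {before:.2f} μm")
print(f"mean net distance after:           {after:.2f} μm")
print(f"max deviation from ground truth:   {err:.2e} μm")
print(f"registration residual (max RMS):   {diagnostics['max_rms_residual_um']:.2e} μm")
print()
print("Before correction, static cells appear to travel several μm because")
print("the fibre itself drifts; after landmark registration their apparent")
print("displacement collapses to the jitter level and every track matches")
print("the static-referential ground truth.")
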