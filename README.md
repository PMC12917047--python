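# fibretrack

Quantitative analysis of muscle stem cells (MuSCs, satellite cells)
live-imaged on their myofibre niche: rigid drift correction of cell
tracks, migration statistics with mobile/static stratification, lineage
reconstruction with division-mode and orientation classification, fate
indexes, and a fully calibrated synthetic-data generator with wild-type
and dystrophic (*mdx*) presets.

It is written for researchers who track myogenic cells on floating
myofibres (or intravitally) and need the downstream numbers: how fast and
how straight cells move once fibre motion is removed, which divisions are
symmetric proliferative (SCDp), symmetric differentiative (SCDd) or
asymmetric (ACD), how long cell cycles last, and what fraction of the
population has committed (Myogenin-positive) by a given time.

## The quantities it computes

For a track with positions p₁ … p_N at frame interval Δt:

- step distances **dᵢ = ‖pᵢ₊₁ − pᵢ‖** and instantaneous speeds dᵢ/Δt;
- **net distance** D = ‖p_N − p₁‖ and **total distance** Σdᵢ;
- **straightness** D / Σdᵢ ∈ [0, 1] (1 = perfectly ballistic);
- **average speed** Σdᵢ / (t_N − t₁), reported in μm/h;
- **turning angles** αᵢ ∈ [0°, 180°] between consecutive displacements.

Cells are classed **mobile** when their mean instantaneous speed exceeds a
threshold (default 0.41 μm/min, the median of pooled log speeds of a
wild-type reference population; `derive_threshold` recomputes it from any
reference group). Before any of this, per-frame rigid transforms —
least-squares (Kabsch) fits of landmark points, or moment-based alignment
of fibre masks — are chained frame-to-previous and applied so that tracks
describe cell motion relative to the immobilised fibre.

On the lineage side, divisions are classified from the daughters' MYOG
status ((−,−) → SCDp, (+,+) → SCDd, mixed → ACD), orientation from the
daughters' fibre contact at mitosis (both touching → planar, one detached
→ perpendicular), and the package reports per-generation cycle times
(with a truncated-likelihood correction for movie-end censoring), the
**differentiation index** (fraction MYOG⁺ of fate-known cells at a time
point), the **proliferation index** N(t_end)/N(t_ref), post-mitotic sister
co-migration, MYOG-onset kinetics and simple shape calls (circularity
4π·area/perimeter², myotube aspect ratio > 2).

Because raw imaging of this kind is too large to ship, the
`fibretrack.synthetic` module generates scenes with known ground truth —
rigid fibre drift, a two-population (persistent-random-walk / jitter)
speed mixture, and stochastic lineages — calibrated so that the pipeline
recovers the published wild-type and *mdx* values (mobile fractions
0.52 / 0.19, mobile speeds 46.4 / 36.4 μm/h, SCDp 54.5 % / SCDd 57.7 %,
differentiation indexes 38 % / 76 %, first division ≈ 47.3 h, later
cycles ≈ 8.5 h).

## A worked example

```python
import fibretrack as ft
from fibretrack.lineage import (cell_cycle_durations, division_records,
                                fate_index_report, mean_cycle_duration,
                                mode_fractions)

preset = ft.preset("wt")
scene = ft.simulate_lineages(preset, n_founders=150, seed=3)
records = division_records(scene.lineage, scene.observed_tracks, fate_mode="labels")
durations = cell_cycle_durations(scene.lineage)
print(mean_cycle_duration(durations, generation=1, censoring_corrected=True))
print(mode_fractions(records))
```

prints (see `examples/lineage_fates.py` for the full script):

```
first-division mean:           46.9 h
later-cycle mean:              8.5 h
division modes:                SCDp 55.1%  SCDd 32.4%  ACD 12.4%
differentiation index (72 h):  39.9%
proliferation index:           6.47
```

i.e. activation takes about two days, subsequent cycles under nine hours,
symmetric proliferative divisions dominate the wild-type spectrum, and at
72 h roughly 40 % of cells are MYOG-positive. The other scripts in
`examples/` demonstrate single-track metrics, landmark-based drift
correction and a wild-type vs *mdx* pipeline comparison; `fibretrack
run-all --preset mdx --out report` runs the same end-to-end pipeline from
the shell.

## Layout

| Module | Contents |
| --- | --- |
| `fibretrack.model` | `Track`, `LineageTree`, `ShapeDescriptor`, validation |
| `fibretrack.io` | tracks CSV and TrackMate-dialect XML readers/writers |
| `fibretrack.registration` | Kabsch point fits, mask moments, transform chains, track correction |
| `fibretrack.motility` | step metrics, summaries, threshold, stratification, sister co-migration |
| `fibretrack.lineage` | division modes, orientation, cycle timing, fate indexes, shape calls |
| `fibretrack.synthetic` | presets, fibre-motion/track/lineage simulators, scene export |
| `fibretrack.pipeline` / `fibretrack.cli` | end-to-end orchestration, tidy reports, thin CLI |

See `docs/methods.md` for the generative model, its calibrations and the
numerical choices.
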