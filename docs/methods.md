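# Methods

## Coordinate and unit conventions

All positions are micrometres in a right-handed frame with the origin at
the image corner; frames are 0-based; time is minutes internally and
hours in reports. Tracks must have strictly increasing frames; gaps are
allowed, but a gap of more than 3 missing frames splits a track into
segments for motility purposes, because step statistics across a long
interruption are meaningless. MYOG status is treated as irreversible
within a movie: a cell is positive from its first positive observation
onward, which matches the behaviour of the differentiation marker over a
72 h window.

## Rigid drift correction

Floating myofibres translate and rotate between frames, so observed
trajectories mix cell motion with fibre motion. The correction is rigid
only — rotation plus translation, no deformable stage — because the rigid
component is the quantitatively defined, verifiable core of the problem;
the generator's fibre motion is correspondingly rigid by default.

Two estimators are provided:

- **Landmark point sets.** The least-squares rigid fit (Kabsch): centre
  both sets, take the SVD of the cross-covariance, and force a proper
  rotation via the determinant sign. Degenerate inputs (fewer than 2
  planar / 3 spatial pairs, coincident points, collinear points in 3D)
  raise errors rather than returning an ill-conditioned fit.
- **Binary fibre masks.** Centroid plus principal-axis alignment from
  second central moments. Principal axes are directionless, so the 180°
  ambiguity is resolved by taking the smaller rotation; this assumes
  inter-frame rotation below 90°, which holds by orders of magnitude at
  realistic drift rates. A mask with axis ratio below 1.05 carries no
  usable orientation and degrades to a translation-only fit with a flag.

Registration is chained frame-to-previous — T_t maps frame t onto frame
t−1 — and accumulated as C_t = C_{t−1} ∘ T_t with C_0 = I, so C_t takes
frame-t coordinates to the frame-0 referential. Accumulated drift is
monitored by re-projecting the landmarks of every frame to frame 0; a
scene whose maximum RMS residual exceeds a threshold (default 5 μm) is
flagged `motility_excluded`: its tracks keep working for lineage analysis
but are marked excluded in motility tables, mirroring how movies with
uncorrectable fibre motion are handled in practice. When a frame's
registration fails outright the previous transform would be propagated
with a flag; with the generator's noise-free landmarks this path is never
exercised.

## Motility statistics and stratification

Definitions are as in the README. Numerical choices:

- Zero-length steps have no direction, so they are skipped in turning
  angles but still counted in distance and speed sums.
- The classification unit is the cell-cycle segment (birth to division or
  censoring); a "merged" row pools a cell's steps across cycles. Mean
  instantaneous speed (= total distance / duration for uniform sampling)
  is compared against the threshold.
- The default threshold is 0.41 μm/min. `derive_threshold` recomputes it
  as exp(median(log s)) over all positive step speeds of a reference
  population. Note that for a mixture with roughly half mobile cells this
  median sits at the lower tail of the mobile mode — a density trough —
  so its sampling variance is large; on 500-cell reference scenes it
  typically lands in 0.26–0.45 μm/min. The fixed default is therefore
  used for classification unless a threshold is derived deliberately.
- Sister co-migration: for each division and offset τ (defaults 30, 40,
  50, 60 min), v_k is daughter k's displacement from the mitosis site at
  t_div + τ; sisters co-migrate when v_a · v_b > 0. An exactly orthogonal
  pair (dot product 0) counts as opposite. Divisions whose daughters are
  not both tracked to t_div + τ are dropped from that offset's
  denominator and reported.

All statistics are invariant under any global rigid transform of a track
(verified by property tests), which is what makes them meaningful after
drift correction.

## Lineage, fates and timing

Division modes follow the daughter-fate rule ((−,−) SCDp, (+,+) SCDd,
mixed ACD; any unknown leaves the division unclassified). Two fate
readouts exist because experiments use both: `endpoint` (status at the
cell's last observation, the retrospective-immunostain convention) and
`live` (positive if any observation between the division and the cell's
own next division or end is positive, which tolerates delayed marker
onset). Classification from generator scenes uses the stored truth
labels. Orientation uses the daughters' fibre-contact flags within the
first two post-mitotic frames.

Cycle durations: generation 1 runs from observation start to first
division; generation k ≥ 2 is the inter-division interval; cells that
never divide are censored and excluded from duration means but counted.
The plain complete-case mean is biased short for late generations — a
cell born late contributes only if its cycle happens to fit before the
movie ends. `mean_cycle_duration(..., censoring_corrected=True)`
therefore fits a normal duration model by maximum likelihood with each
completed duration conditioned on its cell's observation window (a
truncated-likelihood correction); on generator scenes this removes the
≈ 0.2 h shortfall of the pooled later-cycle mean.

The differentiation index is (# MYOG⁺)/(# fate-known) among cells alive
at the query time, with unknowns reported separately; the proliferation
index is the cell-count ratio N(t_end)/N(t_ref) — defined as a count
ratio, consistent with how such indexes are quoted (e.g. a 105 h/21 h
culture ratio of 2.1). Cells lost before a time point do not count at it.

## The synthetic-data generator

The generator produces what the analysis assumes, with full ground truth,
and its presets are calibrated so that the pipeline recovers published
wild-type and *mdx* values. It does **not** synthesise images: masks and
landmarks are generated geometrically, cells are points, and there is no
confinement to the field, no cell–cell interaction, no fusion into
myotubes and no measurement noise on positions. Passing recovery tests
therefore demonstrates that the estimators are correct and calibrated,
not that they are robust to segmentation or tracking errors.

Study conditions baked into the defaults: 10-minute frames, 72 h movies,
a 650 × 120 μm field.

**Fibre motion** is a per-frame random walk: rotation increments
N(0, 0.3°) about the field centre and translation increments N(0, 0.8 μm)
per axis (generator conventions; fast enough that uncorrected static
cells appear to move several μm). Landmarks are 8 fixed points rigidly
co-moving with the fibre.

**Motility mixture.** Each cell is mobile with probability f_mobile
(wt 0.52, mdx 0.19). Mobile cells take persistent-random-walk steps:
heading increments N(0, 30°) per 10-min step and lognormal step speeds
with mean 46.4 (wt) / 36.4 (mdx) μm/h, step-level log-SD 0.25 and a
per-cell lognormal speed factor (log-SD 0.15, unit mean) for cell-level
heterogeneity. Static cells jitter around an anchor with the SD chosen so
their mean apparent step speed is 0.1 μm/min. The spread parameters are
generator conventions chosen so the two speed modes are separated and the
0.41 μm/min threshold falls in the gap; the means and weights are the
calibrated values.

**Timing.** Founders divide after an activation delay N(47.3 h, 10 h)
(wt); later generations after N(mean_g, SD) with mean_g = 8.5 h ×
m^(g−1) and constant coefficient of variation (SD 2 h at 8.5 h), floored
at 1 h. The activation SD is a generator choice consistent with the broad
first-division distributions seen in such cultures. For *mdx*, activation
is 40.4 h — the wild-type mean divided by the measured 1.17 activation
fold-change between the genotypes in grafting assays — and m = 1.2
encodes the progressive cycle slowing of dystrophic cells; both are
calibrations (the per-generation magnitudes are not published as
numbers), fixed so that the endpoint differentiation index matches its
published value.

**Modes and fates.** Each division of a MYOG-negative mother draws a mode
from an (ACD, SCDd, SCDp) multinomial; daughters' fates follow the mode
(the ACD-positive daughter is chosen at random). MYOG-positive cells
divide once more with probability 0.091, always as SCDd. Because those
redivisions add SCDd events on top of the multinomial, the preset stores
the *target* fractions over all classified divisions (wt
12.9/32.5/54.5 %, renormalised from a printed sum of 99.9 %; mdx
14.4/57.7/27.9 %) together with the calibrated share of divisions that
are redivisions (wt 0.048, mdx 0.08), and deflates the drawn SCDd
probability accordingly, so the measured totals land on the targets.
Orientation (planar 68.0 %, perpendicular 18.9 %, undetermined 13.1 %) is
drawn independently of mode, and encoded as daughter contact flags.

**Marker kinetics.** A newly committed (fated-positive) daughter starts
expressing MYOG N(9 h, 2 h) after its birth; a daughter of an
already-expressing mother inherits the marker and is positive from birth.
The endpoint differentiation index read from the expressed annotations is
therefore lower than the fraction of fated cells — exactly as in a real
endpoint measurement, where recently born committed cells have not yet
accumulated detectable marker. With the calibrated timing this emergent
index is ≈ 0.375 (wt) and ≈ 0.75 (mdx) at 72 h, matching the published
38 % / 76 % within sampling error; the wt value is fully emergent (no
free parameter remains on the wt side).

**Post-mitotic dispersal.** For 60 min after mitosis daughters move
ballistically (0.6 μm/min, small heading noise) along headings that are
opposite (±15°) with probability 0.975 (wt) or 0.80 (mdx), then resume
their drawn mobility behaviour. This reproduces > 95 % opposite-direction
sister separation in wild type and a ~20 % co-migrating fraction in
*mdx* at 30–60 min offsets.

Determinism: a single `numpy.random.Generator` seeded from the scene seed
drives every draw in a fixed order, so a (preset, n, seed) triple fully
determines a scene on any platform.

## Acceptance measurements

`scripts/acceptance.py` measures, from fresh simulations: mobile
fractions and mobile mean speed on three 500-cell scenes per genotype
(full register → correct → classify chain); SCDp/SCDd percentages on
300-founder scenes; the mdx endpoint differentiation index on a
1500-founder scene (≈ 5000 cells); and wild-type generation-1 and
generation-≥2 cycle means (censoring-corrected) on a 200-founder scene.
Sub-seeds come from a `SeedSequence` of the given seed. These sizes keep
every stage a few seconds long while leaving sampling error well inside
the tolerances used in the test suite (±0.05 on fractions, 3 SE on
means, 3 binomial SE on percentages, ±3 points on the index).

## Known limitations

- No deformable registration; scenes with genuine non-rigid fibre
  deformation can only be flagged, not corrected.
- The generator's cells are non-interacting points in an unbounded plane;
  quiescent founders move according to their drawn mobility class from
  t = 0 rather than ramping up at activation.
- The mdx per-generation cycle means and the activation mean are
  calibrated, not measured, quantities (see above); conclusions about
  absolute mdx timing should not be read off the presets.
- The derived-threshold operation is statistically fragile near balanced
  mixtures (median at a density trough); prefer the fixed threshold for
  classification.
- Fate reading in `live` mode can miss a positive cell that redivides
  before its marker appears; mode classification from generator scenes
  uses truth labels and is unaffected.
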