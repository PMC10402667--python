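# Methods

## The model

A transit EPID image is treated as a 2-D dose surrogate in Calibrated Units
on a fixed imager-plane grid. The per-fraction composite is the pixel-wise
sum of the fraction's arc images: the panel integrates signal continuously,
so the course-relevant quantity is the fraction total, and summation is
permutation-invariant over arcs. No registration is applied between the
reference and comparison composites — the panel is rigidly mounted opposite
the source, so the image frame is machine-fixed, and any patient change is
exactly the signal of interest.

The GDSA statistic is computed entirely in the reference frame of fraction
one (or of the first fraction of a new plan after a replan):

1. normalize the reference to percent of its own maximum;
2. generalized gradient per pixel, `G_i = sqrt(Σ_j (Δd_ij/Δx_ij)²)` over the
   four nearest neighbours, `Δx` = pixel pitch;
3. segment into four regions with a dose threshold (default 5% of the
   reference maximum) and a gradient threshold (default 3 %/mm);
4. per comparison fraction, GDSA_μ = mean of
   `100·(comparison − reference)/max(reference)` over the high-dose
   low-gradient region; its standard deviation is that of the same pixel
   distribution;
5. flag fractions with `|GDSA_μ|` at or above the tolerance (default 3%).

High-dose low-gradient pixels are the ones where a dose shift reflects a
systematic delivery/anatomy change rather than penumbra jitter: a sub-pixel
positioning wobble in a 20 %/mm penumbra produces huge local differences that
say nothing about target dose, which is why the high-gradient region is
excluded and why the statistic tracks mean target dose.

### Numerical and convention choices

- **Gradient reduction.** The root-of-*sum* over the four neighbour terms is
  the default; `reduction="mean"` (root of the neighbour average) is
  available for sensitivity checks. On a 1-D ramp of slope g %/pixel the
  default gives `G = g·√2/pitch` interior, `g/pitch` on the parallel border.
- **Edges.** Border pixels sum over their 2–3 existing neighbours; no
  padding (replicate padding would fabricate zero-gradient borders).
- **Tie-breaks.** Dose threshold is inclusive (`ref ≥ 5%` is high dose);
  gradient threshold is exclusive (`G < 3 %/mm` is low gradient). The four
  masks therefore always partition the image.
- **Signs.** Difference = comparison − reference: weight loss (increased
  transmission) drives GDSA_μ positive.
- **Spread.** Population standard deviation (ddof 0) over ROI pixels,
  configurable via `std_ddof`.
- **Flag ties.** GDSA flag is inclusive (`|GDSA_μ| ≥ 3%`); the separation
  flag is strict (`Δd_eff > 1 cm`).
- **Degenerate inputs.** All-zero composites, empty ROIs and single-row
  arrays are errors, not zeros — a fraction that cannot be analyzed must
  surface as such. Within a series, a geometry-mismatched fraction becomes a
  NaN record with a note, preserving fraction ordering, rather than aborting
  the course.

## Separation analysis

The body mask on the axial isocenter slice is the largest 4-connected
component above a −300 HU surface threshold (configurable), with internal
holes filled. Separations are bounding-box extents of the mask along the
fixed image axes — `(max index − min index + 1) × spacing` — rather than
chords through the isocenter point: extents are insensitive to the exact
isocenter position and are exactly testable against rasterized phantoms.
Per-axis changes are absolute differences against the reference fraction;
the effective separation change diameter is their geometric mean
`sqrt(Δd_lat·Δd_AP)`, which keeps cm units, is symmetric and monotone in
each axis, and is zero whenever either axis is unchanged.

## Rotation analysis

Pitch is the rotation about the patient left-right axis (x), roll about the
superior-inferior axis (z), yaw about the vertical axis (y). The fixed
convention is extrinsic composition `R = R_yaw · R_roll · R_pitch`; the
decomposition is delegated to a standard quaternion-backed Euler conversion
and is covered by round-trip tests exact to 1e-9° over ±10°, so a convention
change stays localized to one constant. Matrices whose 3×3 block fails
orthonormality or `det = 1` within 1e-6 are rejected as non-rigid. Summaries
(per-axis maximum, mean, population standard deviation) are taken over
*absolute* angles, the form in which setup-error tables are reported; signed
values are retained in the per-fraction CSV for trend plots.

## The synthetic-data generator

`ScenarioConfig` defaults describe one fixed study condition, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_fractions` | 30 | typical radical head-and-neck course |
| `image_size` / `pixel_pitch_mm` | 256 / 0.336 | small enough for fast tests; real panel pitch so gradient magnitudes are realistic |
| `plateau_fraction` | 0.4 | mid-size target field with ample plateau |
| `penumbra_sigma_mm` | 3.0 | megavoltage penumbra scale; peak gradient ≈ 20 %/mm, safely "high gradient" |
| `d0_cu` | 2.0 | transit-signal scale of a ~2 Gy fraction |
| `per_fraction_transmission_gain` | 0.002 | GDSA_μ grows ≈0.2%/fraction, crossing 3% around fraction 16 — the late-course drift pattern of progressive weight loss |
| `contour_axes_cm` | (20, 24) | neck-level A-P × lateral body extents |
| `axis_shrink_cm_per_fraction` | (0.1, 0.1) | ≈3 cm course-total change, within the few-cm maxima seen clinically |
| `rotation_drift_deg_per_fraction` | (0.1, 0.05, 0.05) | accumulates to the few-degree setup regime, pitch dominant |
| `noise_sd_pct` | 0 | exact closed-form tests; set >0 for Monte-Carlo checks |

The reference field is exactly `D0` on a centered plateau rectangle and
decays as `exp(−d²/2σ²)` of the distance `d` beyond the plateau edge, so the
plateau interior has identically zero gradient and the high-dose
low-gradient ROI is guaranteed non-empty. Weight loss is a spatially uniform
multiplicative gain `(1+α_n)`, which exercises every pipeline path while
admitting the exact expectation
`GDSA_μ = 100·α_n·mean(ref over ROI)/max(ref)`; a linear `gain_ramp` across
columns produces nonzero ROI spread like real error bars. Noise is additive
Gaussian in CU (clipped at zero). The `replan` scenario regenerates the
delivery and resets both the analysis reference and the gain baseline at
`replan_at`, reproducing the flags-before / quiet-after re-baseline pattern.

What the generator does **not** emulate: beam/patient attenuation physics
(no CT-to-EPID forward projection), anatomical deformation (the contour
change is a pure affine shrink), correlated detector noise, output drift of
the machine, or setup *translations*. Passing recovery tests therefore
demonstrates that the analysis chain is correct and self-consistent — not
that the 3% threshold has any particular sensitivity/specificity on clinical
images, which requires patient data.

## Problem sizes in the test and acceptance suites

Closed-form and recovery tests run on 96–128-pixel composites, 10–30
fraction courses, 1 mm contour grids, and 50-seed Monte-Carlo repeats; the
brute-force gradient oracle runs 100 random 32×32 images and the mask
partition property 1000 random images. These sizes make every numerical
property land on its analytic bound (the closed form is exact at any image
size) while the whole suite completes in seconds.

## Known limitations

- Using fraction 1 as the reference bakes any day-one setup error or
  anatomy change into the whole course; the mitigation is clinical (offline
  review of the first CBCT), not algorithmic.
- Separation extents are 2-D (single slice) bounding boxes; superior-
  inferior change and localized deformation are invisible to them.
- The rotation convention is an explicit choice; registration matrices
  produced under a different Euler convention must be converted before
  analysis.
- The cohort-level tooling reports exact computed percentages; rounded
  shares in a printed table may disagree in the last digit.
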