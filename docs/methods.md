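# Methods

`octcoreg` implements an automated analogue of a two-stage co-registration
workflow for validating handheld in vivo OCT of the breast surgical cavity:
in vivo tiles → wide-field ex vivo OCT of the excised cavity shaving →
bread-loaf histology, with quantitative micro-elastography (QME) computed
from the same volumes.  This note records the models, the parameters that
matter, and the choices made where the design was open.

## Coordinate and data model

Volumes are `[z, y, x]` arrays with physical voxel spacings in micrometres;
`z` grows with depth.  A B-scan is a `(z, x)` slice, an en face plane a
`(y, x)` slice.  Intensities are linear and non-negative; `NaN` is the
no-data sentinel (e.g. unstitched mosaic voxels).  Decibel conversion
(`10·log10`, floor at 10⁻⁶ of the maximum) is used only for display and for
registration preprocessing.  On disk a volume is a z-paged TIFF with a JSON
sidecar carrying spacings, role, tile id and origin; there is no universal
OCT container format, and this pairing is lossless and readable everywhere.
Stored bit depth of acquired data is assumed 16-bit; the phantom writes
float32.

## Surface detection and en face extraction

All co-registration happens on en face planes sampled at a fixed offset
*below the tissue surface* (100 µm by convention), so the surface is found
per A-scan as the first crossing of an adaptive threshold: the first depth
where the axially median-filtered intensity exceeds `0.3 ×` the column
maximum, followed by lateral median smoothing over 50 µm.  Columns whose
maximum stays below 5 % of the volume maximum carry no surface (out of
imaging depth — such regions occur on real shavings with strong topography
and are exactly what made some clinical tiles unregistrable).  Depth
sampling is nearest-voxel: the 100 µm offset is ~30× the axial pitch of the
real systems, so axial interpolation is immaterial.  For phantoms without a
silicone layer no layer-skip logic is needed; the detector finds the first
tissue interface.

## Fiducial detection

The cavity suture is a bright, elongated ridge near the surface.  The
detector is classical: white top-hat at suture scale (structuring disk
~0.75× the maximum expected width), hysteresis thresholding (0.25/0.5 of the
top-hat peak), connected components, then gates on physical width (default
100–600 µm) and elongation (length/width ≥ 3).  Centroid and axis come from
intensity-weighted second moments; the axis is undirected, reported in
(−90°, 90°] from +x.  Confidence is the normalized contrast
`(µ_comp − µ_bg)/(µ_comp + µ_bg)`, which decreases monotonically with added
noise.  With several candidates (a long orientation suture may also lie in
the field) the best-confidence mark is returned with a multiplicity flag;
the caller disambiguates from the session notes, as in the clinical
workflow.

## Mosaic placement

Coarse placement anchors the suture tile: its detected suture centroid is
mapped onto the ex vivo suture centroid with initial yaw equal to the signed
difference of the suture axes; remaining tiles are offset by
`(Δcol, Δrow) × nominal step` (default 5 mm) in the anchor's rotated frame.

Refinement is an exhaustive rigid search maximizing **masked normalized
cross-correlation** between dB-scaled, surface-flattened en face planes:
yaw ±10° in 0.5° steps, depth offset ±200 µm in 2-voxel steps (the
automated analogue of scrolling en face depths when the probe was tilted or
pressed harder), translation ±2 mm.  The NCC is computed for all
translations by FFT with the Padfield masked formulation, so no-data pixels
of either plane never contribute; shifts with under 25 % valid overlap are
excluded, and a tile with no admissible shift is unregistrable
(score −1).  Both planes are lightly smoothed (masked Gaussian, σ = 1
wide-field pixel) before correlation: raw speckle makes the score landscape
noisy in yaw, and this smoothing removed a tail of ~1.3° yaw errors without
affecting translation accuracy.  The best grid translation and yaw are
refined below grid resolution by local quadratic fits.  Ties break toward
smallest |yaw|, then |dz|, then displacement from the initial pose.  NCC is
invariant to affine intensity rescaling, which is why it is the right
similarity for two OCT systems with unrelated intensity scales.

Tissue classification follows the 90 % field-of-view rule: per-pixel class
from local mean dB against the plane's bright level (adipose backscatters
weakly), then "dense"/"adipose" when one class exceeds 90 %, else "mixed".

Success is an automated surrogate for the study's two-rater agreement: the
correlation score must clear a threshold (default 0.3) **and** the placement
must be consistent with already-placed grid neighbours (mean residual
against the nominal-step offsets, rotated by the pair's mean yaw, within
1.5 mm — adjacent tiles share ~1 mm of overlap by construction, so a decoy
optimum several mm off-grid fails this gate even with a plausible score).
Both thresholds are configuration defaults, not published values.  Tiles
flagged `poor_contact`/`blood` in the session log are registered normally
and reported with their flags.

## Wide-field stitching

Benchtop stage positions are trusted as hardware-accurate (no cross-tile
registration).  `plan_tiles` picks the smallest per-axis count with
`fov + (n−1)·step ≥ extent`; `stitch` blends tiles with weights ramping
linearly from each tile edge (feather width defaults to a quarter of the
tile), normalized so weights sum to one wherever any tile contributes.
Tiles cut from one volume therefore re-stitch to it voxel-for-voxel, and
blended values in overlaps are convex combinations of the contributors.

## Quantitative micro-elastography

The mechanical model is uniaxial (series springs): stress is constant along
each A-line and equals the surface stress measured through a
pre-characterized compliant layer.

* **Displacement** between the compression states is windowed 1-D
  zero-mean NCC along depth (default window 150 µm, search ±4 voxels) with
  sub-voxel refinement by a *Gaussian* (log-parabolic) fit of the
  correlation peak.  A plain parabola peak-locks on speckle (quarter-voxel
  shifts estimated as ~0); the log fit removes the bias, a standard result
  from particle-image velocimetry.  Confidence is the peak correlation.
* **Strain** is the slope of a confidence-weighted least-squares line fit
  of displacement over a moving axial window (default 100 µm as an
  operation; the full chain uses 150 µm).
* **Layer stress**: the layer strain is measured by a direct line fit of
  displacement across the layer interior, keeping half a correlation window
  clear of the window edge (padded correlation windows bias slopes low) and
  of the layer/tissue boundary (bright tissue entering the window).  The
  monotone stress–strain characterization is evaluated by piecewise-linear
  interpolation; strains outside the characterized range raise unless
  extrapolation is enabled.
* **Elasticity** is stress/strain per voxel, in linear kPa; |strain| below
  10⁻⁴ is treated as noise and masked.  Log-scale display is a rendering
  flag only.
* **Masking** follows the clinical segmentation: a lateral (per-A-line)
  rule.  Each column is summarized by its median dB over the shallow
  tissue band (first 500 µm below the layer — deeper, differential
  attenuation makes dense tissue as dark as fat and the contrast inverts),
  pooled over 200 µm (at least an adipose cell diameter, so bright septum
  columns average with the dark interiors around them).  A column is
  adipose when the pooled mean sits below −2 dB of the lateral bright
  reference *and* the pooled standard deviation exceeds 0.8 dB (the
  honeycomb-texture confirmation; dense speckle pools far smoother).
  Columns with layer strain below 10⁻⁴ are non-contact.  Loosening any
  threshold never unmasks a voxel.

The displacement sign convention is the imaging frame: the window at z = 0
is the fixed reference, so material moves toward it and |u| accumulates
with depth, reaching the actuation at the base.  Compressive strain is
−du/dz; the chain handles signs so elasticity is positive.

## Histology mapping

Sections are bread-loafed orthogonally to the en face plane, so each slide
corresponds to a B-scan.  The section grid places equally spaced lines
(spacing ~4–5 mm) across the specimen along y, first line at half-spacing
from the specimen edge; a flipped inking code mirrors the order.  The
shrinkage correction factor is `c = fresh width / section width`, one
factor per slide (shrinkage varies across a shaving; variation *within* one
slide is not modelled).  Fresh width is measured from the specimen mask in
OCT.  B-scan selection rescales the slide by `c` and maximizes the Dice
overlap of binary solid-structure maps (threshold at 30 % of the bright
level) over B-scans within ±1 mm of the grid line, ties breaking toward the
line.  Structure overlap, not intensity correlation, is used because
histology and OCT intensities have unrelated semantics; the nonlinear
histology warp is deliberately *not* inverted — only the rigid rescale plus
index search, mirroring the manual procedure.

## The phantom: what it emulates, and what it does not

The generator reproduces the image features the pipeline actually relies
on: bright dense stroma with smooth ±22 % texture (correlation length
700 µm) attenuating exponentially with depth (default 2 mm⁻¹); adipose as a
Voronoi honeycomb (cells 60–120 µm, 5 µm Gaussian-ridge septa, interiors at
~4 % of dense reflectivity) extruded in depth; a suture ridge raised above
the surface and very bright; tubular vessels/nerves (dark lumen, bright
wall); smooth surface topography; fully developed speckle as multiplicative
exponential noise (contrast 0.7) under a 0.75-voxel PSF blur.  Ground truth
(class map, suture pose, elasticity, surface) accompanies every volume, and
one seed fixes everything bit-exactly.

In vivo degradation when cutting a handheld tile: additive noise, lateral
blur (coarser handheld optics), a blood film (surface brightening +
attenuation), probe tilt (a linear depth ramp across the tile), and a
smooth elastic lateral warp modelling tissue deformation between the cavity
and benchtop acquisitions.  The warp is what makes adipose-only tiles fail
realistically: blur and noise alone leave the honeycomb a shared
fingerprint that registers easily, whereas deformation at 150 µm amplitude
and 300 µm scale decorrelates cell-scale detail while dense-tissue texture
survives — reproducing the clinical ordering (dense ≈ mixed ≫ adipose).

The compression simulator stacks a speckled layer band on top of the
volume, band-limits axially (σ = 1.2 voxels, an imaging-PSF stand-in —
sub-voxel warps of near-white speckle are not representable), solves the
series-spring balance per column by sampled monotone inversion of the layer
curve, and warps each A-line by the resulting displacement field.

Not emulated: wave-optics/Monte-Carlo speckle statistics, refraction at the
probe window, H&E colour (sections are grayscale structure maps), realistic
suture knots, 3-D adipose cell packing (the honeycomb is extruded), and
intra-slide shrinkage variation.  Passing phantom tests therefore shows the
*mechanics* of the pipeline are correct under controlled conditions, not
that the detectors' default thresholds are optimal on clinical images.

## Study conditions of the benchmarks

`octcoreg.evaluation` freezes the phantom-study conditions used by the test
suite and `scripts/acceptance.py`:

* pose recovery: 20 mixed-tissue phantoms (7×7×0.9 mm at 30/10 µm pitch),
  pose jitter ±500 µm and ±5°, SNR 10 dB, no blur; recovery = within
  2 lateral voxels and 1°;
* tissue-type ordering: 8 phantoms per class under the cross-system
  degradation (60 µm blur, SNR 12 dB, 150 µm elastic warp), success = score
  ≥ 0.3;
* QME: 2×2×1.5 mm phantoms at 40/10 µm, 500 µm linear layer, 30 µm
  actuation; homogeneous 20 kPa and a 20/10 kPa two-layer stack;
* histology: sections at 2.5–4.5 mm spacing, shrink 1.1–1.25, warp 30 µm.

These sizes keep a full sweep within minutes on one core; all geometric and
contrast parameters are physical, so behaviour transfers to full-scale
volumes (a full-scale wide-field volume is ~5 × 10⁹ voxels and is supported
by the same code paths, just slower).

## Numerical notes and edge cases

* Masked NCC guards: overlaps below 16 pixels or 25 % of the tile are
  rejected; variances are clipped at 0; NCC clipped to [−1, 1].
* Sub-voxel displacement refinement is skipped where the correlation peak
  is exactly 1 (identical windows): the log fit is ill-conditioned there.
* `argmax`-based first-crossing surface detection resolves ties toward the
  shallowest depth, which is the physically correct choice.
* Stitching accumulates in float64 and divides by the summed weights, so
  agreeing tiles reproduce their source to float32 precision exactly.
* Percentages in the success table round half away from zero to the
  printed integer.
* Empty sessions, duplicate grid cells, unknown note flags, non-monotone
  layer curves, zero-dimension volumes, spacing mismatches and
  out-of-range actuation all raise typed validation errors rather than
  propagating silently.
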