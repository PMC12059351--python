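# Methods

This note documents the models, conventions, parameters and numerical
choices behind `ecmbridge`, and what the synthetic phantoms do and do not
establish about real microscopy data.

## Raster conventions

Rasters are ordered (z, y, x) with the origin at the top-left pixel; x
indexes columns, y rows; intervals are half-open; micron↔pixel
conversions round half away from zero. Angles are degrees
counter-clockwise from the +x image axis and axial (mod 180°): because
the raster y axis points down, an angle θ corresponds to the pixel
direction (cos θ, −sin θ) in (x, y). The scene generator and all
estimators share this convention.

## Remodeling densitometry

The remodeling score of a well is the mean reflection intensity per
included pixel inside a cell-free rectangular ROI placed at the midpoint
between the two clusters, computed per Z-section and averaged across the
stack. Mean-per-pixel (rather than summed) intensity makes scores
invariant to ROI size; totals are recoverable by multiplying with the
pixel count. The default ROI is 100 µm × 40 µm, axis-aligned, long side
along the inter-cluster axis; bright artefact discs (reflections from
optical elements) are excluded by a mask, and if the rectangle overlaps
an artefact it is shifted along the inter-cluster axis to the nearest
clear position. No background subtraction is applied by default; a fixed
offset is available. Foreground restriction (per-section Otsu) is
optional and off by default, since the mean over a fixed ROI is already
comparable across conditions imaged with one protocol. The score is
exactly linear in global intensity scaling.

## Orientation estimation

Per-pixel fiber orientation uses the structure tensor
J = G_σi ∗ (∇I ∇Iᵀ). Gradients are derivative-of-Gaussian filters at a
derivation scale of 1 px — plain central differences are measurably
anisotropic on fibers near the pixel scale (errors >10° toward the
diagonals on 1-px anti-aliased lines), while the 1-px Gaussian
derivative keeps recovery within ~0.3° at arbitrary angles. The
integration scale σi defaults to 3 µm, about twice the nominal fiber
width, converted to pixels via the image's pixel size. The fiber axis is
the minor eigenvector of J (orthogonal to the dominant gradient); the
confidence weight is coherence (λ₁−λ₂)/(λ₁+λ₂+ε) multiplied by the
tensor trace normalized to its per-section maximum, giving weights in
[0, 1] with flat background at 0.

## Alignment index

The scalar alignment summary is the weighted mean resultant length of
doubled angles, R = |Σ w e^(i2θ)|/Σ w — the standard axial-statistics
concentration measure, bounded in [0, 1], equal to 1 for a single shared
axis and 0 for balanced distributions. This definition is deliberately
simple and testable; it is not numerically identical to the coefficient
produced by curvelet-based tools, though both rank angular concentration
the same way. The quadrant protocol evaluates four corner ROIs
(250×250 px by default, shrunk with a flag on smaller sections) in every
Z-section, restricts weights to Otsu-foreground pixels, averages the
four per-ROI values within a section and then across sections.
"Aligned-fiber intensity" is the mean intensity of foreground pixels
whose axial distance to the weighted dominant angle is ≤ 10°.

For an isotropic sample the expected resultant length is ≈ 0.89/√n for n
independent fibers, so isotropy checks are only meaningful when each ROI
contains a few hundred fibers; the isotropic phantoms used in the tests
are sized accordingly (fiber density 80 per 100×100 µm, ~720 fibers per
120-px ROI at 2.5 µm/px).

## Cell directionality

Protruding cells are detected in the F-actin channel by Otsu
thresholding after excluding cluster-body pixels via a mask (the paper
trail for how cluster bodies were delineated is thin everywhere; the
mask-based exclusion is this package's operationalization, and the
synthetic truth provides the mask). Connected components ≥ 20 µm² each
receive the weighted axial mean of their orientation-field angles.
Orientation histograms use 2° bins on [0, 180); the Gaussian fit
A·exp(−d(θ,µ)²/2σ²)+b wraps the angular offset on the 180° period (no
edge bias at 0/180) and reports goodness = max(0, 1 − SS_res/SS_tot),
clamped to [0, 1]; fewer than 5 non-empty bins, a flat histogram
(SS_tot = 0) or non-convergence yield an invalid fit with goodness 0.
The aligned proportion counts cells within ±10° (axial) of the reference
fiber angle per Z-section and averages sections; sections without
detected cells are excluded from the mean (scoring them 0 would conflate
absence with misalignment) and flagged. The reference angle is measured
per scene by running the orientation field on the bridge ROI rather than
taken as a constant.

## Viability scoring

Each Hoechst section is lightly smoothed (Gaussian, 1 px), Otsu
thresholded, hole-filled and split by a distance-transform watershed
seeded at maxima of the smoothed distance map with ≥ 4 µm separation;
components < 12 µm² are dropped. A section whose Otsu threshold does not
reach twice the median intensity is treated as nucleus-free — without
this guard, sections containing no nuclei get thresholded inside the
background noise and produce hundreds of spurious objects. Each object's
mean PI intensity is compared to a threshold computed by exact Otsu over
the object means — the between-class-variance-maximizing split of the
sorted sample. (The histogram formulation of Otsu is unstable on the
small, strongly bimodal samples of per-object means — a few dozen values
per section — and can land inside a mode; the exact split cannot.) When
all objects fall on one side of a background-referenced cut (3× the
median of the PI section), i.e. the section is all-live or all-dead,
that cut is used directly and flagged, since a two-class split does not
exist. Per-section PI-positive proportions are averaged over sections
with ≥ 1 nucleus, matching the per-section workflow of the assay;
segmentation is 2D per section (not 3D), so a nucleus spanning sections
counts once per section — consistent across conditions, leaving
proportions comparable.

## Synthetic scenes

The generator emulates the assay geometry: two 200-µm clusters of 500
cells at 900 µm spacing; reflection Z-sections every 25 µm; viability
sections every 10 µm; fiber peak 200 intensity units over background 5
with Gaussian noise SD 4 (2 % of peak) and optional Poisson resampling;
bright artefact discs at configurable positions. Specific choices:

- **Fibers** are per-section 2D anti-aliased segments (default 40 µm),
  composited by maximum so crossings do not double intensity; the
  analysis itself is per-section, so 3D tube rendering would add cost
  without changing any readout. Orientations follow a von Mises law on
  doubled angles (mean `bridge_axis_angle`, concentration `kappa`;
  kappa = 0 is uniform). Per-section fiber counts are Poisson with mean
  density × area.
- **The bridge** is a corridor (default 120 µm wide) joining the two
  cluster rims, laid along +x, with aligned fibers (concentration 8) at
  density `bridge_fiber_density × multiplier` replacing the isotropic
  background field inside the corridor; the multiplier interpolates
  between the unstimulated control (0.1) and the stimulated control
  (1.0). The real assay gives no quantitative bridge geometry; width,
  density contrast and corridor concentration are assumptions of this
  generator, stated here.
- **Nuclei** are dart-thrown into the cluster sphere with ≥ 1 diameter
  3D separation plus a lateral-separation constraint within each
  Z-section bin, rendered as Gaussian blobs (radius 5 µm, σ = r/2) in
  their nearest section. Exactly round(dead_fraction × n) nuclei are
  PI-bright, apportioned across Z-bins by largest remainder (dead cells
  have no preferred depth) with the within-bin choice seeded.
- **Protruding cells** are rods (30 µm) at the corridor-facing cluster
  rims, orientations von Mises around the bridge axis when "treated" and
  uniform under the control flag; cluster bodies are F-actin-bright and
  covered by the truth's cluster mask.
- **Reproducibility**: one integer seed; per-channel sub-streams are
  derived with fixed offsets, so identical config + seed gives
  bit-identical scenes, channel by channel.

## Simulated screens

A screen covers each compound at 6 concentrations (index 1 = highest;
1:3 dilution steps, top dose 243 in units of the lowest) with 3
replicate wells and shared CTR/TGFB control triplets. Planted
pharmacology is Hill-shaped: efficacy e(c) = c^h/(c^h+EC50^h) (optionally
× (1 − loss(c)) for bell-shaped, high-dose-loss responses) scales the
bridge multiplier; toxicity adds to a 0.02 baseline dead fraction,
clipped at 0.95. Two presets mirror screening archetypes: a
"ROCKi-like" compound (efficacy EC50 5, Hill 2; toxicity max 0.8, EC50
20, Hill 4 → toxic at the top three doses, one clean effective dose) and
a "TbRi-like" compound (efficacy EC50 15, Hill 3 with loss EC50 150,
Hill 4 → effective only at mid doses, no toxicity, non-monotone).
Expected inhibition is analytically 100·e(c), because the measured score
is linear in the planted multiplier up to fiber-overlap saturation, so
`analytic_windows` provides an independent oracle for window detection.

Screen wells are quantified on a 300 µm × 80 µm ROI with corridor
density 12 fibers per 100×100 µm: the ROI mean is a Poisson average over
~50 fibers, keeping the replicate-mean inhibition within a few percent
of the planted value — comfortably inside the ≥ 15-point margins the
preset compounds leave around the 50 % efficacy threshold. Window
detection is per-concentration classification (inhibition ≥ 50 %,
toxicity ≥ 0.2 by default — pipeline defaults, not assay constants),
never curve fitting, because the non-monotone compound would break a
monotone fit; a Hill fit is provided for description only. The three
call sets partition the tested indices by construction.

## Problem sizes

Test and acceptance phantoms are sized for statistical sufficiency at
desk scale: orientation checks on 128² stripe images; alignment sweeps
on 3-section 300² fields (~2 400 fibers per section); viability on full
21-section clusters of 500 nuclei; screens of 2 compounds × 6 doses × 3
replicates + 6 controls (42 wells, each a 3-section bridge scene plus a
9-section viability stack covering the central 80 µm of one cluster).

## What the phantoms do not show

The generator reproduces the geometry and statistics of the assay, not
its optics or mechanics: no point-spread function, refraction or depth
attenuation; no mechanical fiber remodeling or cell migration; nuclei
are ideal Gaussian blobs without shape variation, debris or staining
heterogeneity; fiber "bridges" appear by construction rather than by
contraction. Passing tests therefore demonstrate that the estimators
recover planted truth under controlled imaging statistics — they do not
certify performance on real confocal stacks, where segmentation and
thresholding parameters (minimum area, seed separation, contrast guard,
background factor) may need retuning. The alignment index is also not
numerically interchangeable with curvelet-based alignment coefficients.
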