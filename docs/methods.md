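# Methods

`stainmap` reconstructs a 3D stain volume from serial 2D histological
sections, extracts equi-volume cortical-depth staining profiles inside
regions of interest (ROIs), and quantifies how well pairs of ROIs can be
told apart histologically, using bootstrap distributions of Cohen's d
compared across conditions with two-sample Kolmogorov–Smirnov (KS) tests.
This note describes the models and algorithms, the synthetic phantom that
the test suite runs everything against, the numerical choices, and the
known limits of what passing tests demonstrate.

## The measurement model

The raw data are alternating cytochrome-oxidase (CO) and myelin
(Gallyas-type) stained sections cut at 50 µm, digitized as 8-bit grayscale
with non-brain pixels at 0. Throughout the analysis, intensities are
converted to *darkness* `d = 1 − raw/255`, so 0 means unstained and 1 the
darkest staining; the linear flip is the minimal realization of that
convention.

Each section is modeled as a rigidly misaligned, intensity-shifted
rendering of an underlying smooth tissue volume:

- a per-section 2D rigid transform (rotation + translation) from the
  cutting/mounting process;
- a per-section additive intensity offset that varies smoothly with
  section index (staining-batch drift) plus high-frequency deviations;
- pixel noise and a smooth within-tissue texture.

## Reconstruction

**Segmentation.** Brain pixels (non-zero) are split into two classes by
exact multilevel Otsu thresholding of their histogram (exhaustive
between-class-variance maximization over all cut tuples; ties broken
toward the lowest cuts). Gray matter (GM) is the class with greater
4-connected contact with the image background — the cortical ribbon abuts
the outside of the brain, the white matter (WM) does not. Labels follow
the 0/127/255 (background/GM/WM) convention; the outer (pial) and inner
(GM/WM) boundaries are GM pixels 4-adjacent to background and WM
respectively. GM islands under 50 px are folded into WM before boundary
extraction.

**Serial rigid alignment.** Sections are aligned serially, ascending and
descending from a middle reference section. Each neighbor pair of *raw*
sections is registered in two stages — (1) binary brain masks, mean
squares on lightly smoothed masks, centroid-initialized with a coarse
rotation scan and Powell refinement; (2) mutual information (32-bin joint
histogram) between the Gaussian-smoothed 0/127/255 label images, seeded by
stage 1 — and the per-section transform is the composition of the pairwise
results toward the reference. Estimating raw pairs keeps image resampling
out of the estimation loop; resampling happens once, when the composite
transforms are applied to the original stain images (bilinear) and label
images (nearest). Both optimizers are deterministic (no stochastic
sampling). The smoothing before the MI metric matters: on categorical
images, the MI optimum can sit a fraction of a pixel off truth due to
boundary rasterization, and a σ = 1 px blur removes that bias.

On a geometry-static phantom the procedure recovers planted transforms to
better than 0.4° and 0.5 px. When section shapes genuinely vary from
section to section, per-section segmentation rasterization adds an
irreducible ~0.3–0.5 px per-link uncertainty which random-walks along the
chain (a few px over 30 sections, direction-free); adjacent sections
remain registered to each other at the single-link accuracy, which is what
the downstream depth analysis uses.

**Drift correction.** Per stain, a quadratic in section index is
least-squares fitted to the per-section mean brain intensity, and each
section is shifted additively by (fit − mean): corrected means lie exactly
on the fit, and within-section contrasts are untouched (an additive shift
cannot change pixel differences). The correction deliberately allows
gradual drifts (e.g., from varying GM/WM area ratios) while removing
section-to-section jumps; its known cost is that genuine per-section
differences in the whole-section mean are transferred into every ROI's
mean as a shared component.

**Stacking and reference alignment.** Aligned, corrected sections are
stacked per stain and the section axis linearly interpolated to isotropic
voxels. The stain volume is aligned to an anatomical reference volume with
a mutual-information affine registration (SimpleITK, gradient-descent line
search, multi-resolution, deterministic regular sampling), optionally
refined by a symmetric-forces demons displacement field (off by default;
the affine suffices for generated geometry). Alignment is validated by
Pearson-correlating corresponding slices over in-brain voxels against a
null distribution of non-corresponding pairs (seeded subsample above
10,000 pairs). CO is compared on the intensity scale and myelin on the
darkness scale so both correlate positively with T1-like contrast.

## Laminar geometry

**Equi-volume depth.** Per GM component: (1) an equidistant field
`α = d_outer/(d_outer + d_inner)` from Euclidean distance transforms to
the two boundaries; (2) a tangential coordinate — mid-depth pixels
(α ∈ [0.45, 0.55]) are skeletonized and ordered along their run, and every
GM pixel is traced along the (bilinearly interpolated) gradient of the
smoothed depth field to its mid-layer landing point, whose arc position it
adopts. Streamline tracing in the continuous field avoids the grid
anisotropy of pixel-neighbor schemes. (3) Within tangential columns of
20 px (500 µm) arc, the continuous depth of a pixel is its area rank of α,
so each of the K = 15 depth bins encloses equal tissue area in every
column. Because this is a cumulative-area inversion, it is invariant to
any monotone depth field and reproduces the closed-form equal-area law on
an annulus (`r_k = sqrt(r_out² − (k/K)(r_out² − r_in²))`) to well under a
pixel, with bin boundaries strictly closer to the convex outer surface
than equidistant ones — the signature of outer layers thinning over gyral
crowns. Per-pixel continuous depth is quantization-limited: at a 40 px
thick ribbon one pixel ring spans ~0.025 of depth, so per-pixel agreement
with the closed form is ~0.01 mean / ~0.04 at the 99th percentile, not
arbitrarily small. Columns with fewer than K pixels are merged into their
nearest valid column and logged.

K = 15 follows the granularity at which a band occupying a tenth of the
depth is isolated into 1–2 bins. Bin 1 is outermost; "outer" and "inner"
summaries average bins 1–7 and 8–15.

**Columnar distance.** Within an ROI, the mid layer (α ∈ [0.40, 0.60]; a
wider window than the depth-bin mid band because the 2–3 px band of a
narrower window can pinch apart on resampled masks) is reduced to a chain
whose geodesic arc length is measured from one end (deterministic
orientation: the end with the smaller image coordinates); every other ROI
pixel inherits the distance of its nearest mid-layer pixel (Euclidean),
and distances are cut into columnar bins (default 5 px). A disconnected
mid layer inside the ROI is an error, reported with the component count.

## Profiles, maps and statistics

**Depth profiles.** Per section and ROI, mean darkness per depth bin;
sections where the ROI misses GM are excluded and logged. The section
intensity used by all group statistics is the mean over bins (all, outer 7,
or inner 8). ROIs given as partial-depth masks are extended
perpendicularly to cover the full depth: all GM pixels whose tangential
arc coordinate falls in the ROI's arc interval are included, at pixel
resolution (so sub-column ROI displacements are preserved), restricted to
connected patches touching the ROI. The extension is idempotent.

**Between-ROI tests.** Classical pooled-variance unpaired two-sample
t-tests on section intensities, with Benjamini–Hochberg FDR (q = 0.05)
applied over the whole comparison family. Laminar pattern similarity is
the Pearson correlation of two mean 15-bin profiles.

**Tangential (2D) maps.** Per section, darkness is collapsed across depth
within each columnar bin, bin centers are rescaled to [0, 1] by the
section's mid-layer arc length, values are linearly interpolated onto a
common tangential grid, and sections are stacked as rows. The non-face
intensity at each tangential position is the mean over sections whose
cortex at that position lies outside every ROI; each ROI bin's difference
is its darkness minus that positional non-face mean. By construction this
subtraction cancels any purely tangential additive gradient, which is the
control for broad staining gradients masquerading as ROI effects.

**Bootstrap discriminability.** For each ROI pair and condition, 10,000
bootstrap iterations resample the per-section intensities with
replacement (group sizes preserved) and record Cohen's d (unbiased pooled
SD; no small-sample correction, which is exposed as an option).
Iterations with zero pooled SD are redrawn (capped, logged) so the vector
length is exact. The per-group resampling streams are bound to the group
contents rather than argument order, making the d distribution exactly
antisymmetric under group swap. Two conditions of the same pair use the
same seed, so identical condition data give KS distance 0. The three
condition contrasts are CO vs myelin, outer vs inner depths, and
individually vs probabilistically defined ROIs; each is summarized by
Δd = mean d(cond 1) − mean d(cond 2) and a two-sample KS test (asymptotic
p) between the d distributions. Note that the bootstrap mean of d is
biased upward relative to the sample d when the true effect is large
(size-n resamples underestimate variance); at d ≈ 1 and n = 12 the bias
is below 0.15, at d ≈ 4 it reaches ~0.5–0.8 — a property of the
resampling scheme itself, reproduced exactly by an independent plain-loop
oracle.

**Group level.** Mean depth profiles are pooled across hemispheres per
ROI (n = bins × hemispheres), fitted with a normal PDF by sample
mean/SD, and compared pairwise by two-sample KS tests under a Bonferroni
family-wise correction (the family-wise reading of the procedure; BH is
available by option). With AL and AF/AD patches differentiating
inconsistently, their mutual pair is excluded from the bootstrap
contrasts by default and can be enabled by configuration.

## The synthetic phantom

The phantom emulates one hemisphere's serial 50 µm sections at 25 µm
pixels on a 192×192 grid: a circular-arc cortical ribbon (inner radius
42 px, outer 70 px, ~200° span) over a WM core, with a WM "brainstem"
stub on the free side that anchors rigid rotation (a pure arc is
rotationally ambiguous when its span varies). Geometry varies slowly with
section index (radial shrink, span shrink away from the middle, small
random span/radius wiggle) so non-corresponding slices are geometrically
distinguishable. Laminar profiles are planted as functions of equi-volume
depth — the coordinate the pipeline measures — with CO carrying a broad
mid-depth band and myelin a monotone depth ramp; the standard conditions
plant a +0.08 CO and +0.02 myelin darkness offset in the ML patch,
confined to the outer seven bins. Three disjoint face-patch ROIs (ML, AL,
AF/AD) occupy fixed angle intervals over staggered section ranges, kept
clear of the ribbon's end caps. Jittered ROI copies stand in for
probabilistic atlas definitions: one displacement per ROI per hemisphere,
directed along the ribbon tangent (localization error runs along the
cortical sheet; radial error would be nullified by the depth extension),
with magnitude drawn to land in the Dice ≈ 0.5–0.7 overlap regime of
real individual-vs-atlas patches. A within-tissue texture (amplitude
0.03 darkness, 1.5 px scale, tapered to zero at class boundaries so it
cannot blur the GM/WM/background transitions, sign chosen per stain) is
shared with the T1-like reference volume and is what makes corresponding
histology/reference slices correlate above non-corresponding ones.
Misalignments (≤4°, ≤8 px), quadratic-plus-alternating drift, and pixel
noise (σ = 0.01) complete the raw sections. Raw sections are rendered
analytically in the misaligned frame (no interpolated class boundaries);
darkness and drift offsets are quantized to the 1/255 export grid so the
drift ground truth survives the 8-bit export exactly. Class intensity
levels keep GM and WM separable by thresholding in both stains, including
under the texture — the myelin margins in particular (WM darkness 0.84 vs
deep GM ≈ 0.57) are what keep segmentation, and everything downstream of
it, stable.

What the phantom does **not** emulate: tears, folds and missing tissue;
realistic cytoarchitecture; nonlinear section distortions; anatomy shared
between adjacent sections (textures are independent per section); the
real study's data scale (768×1024 px sections, multiple hemispheres). A
passing suite therefore demonstrates correctness of the algorithms and
recovery of planted effects under controlled nuisances — not performance
on real histology, whose printed values (registration correlations
≥ 0.835, specific Cohen's d and KS distances, Dice 0.217–0.578) require
the deposited data and are out of scope here.

## Reported problem sizes

The standard phantom run uses 30 sections (15 per stain), 10,000 bootstrap
iterations, and the 50-transform planted-recovery battery; these sizes
keep every quantity's Monte-Carlo error well inside its decision margin
while the full suite runs on a single CPU.

## Known limitations

- Per-pair directions for the weak (myelin, +0.02) individual-vs-
  probabilistic contrast sit at the single-hemisphere noise floor;
  direction recovery is asserted on the pooled (collapsed across pairs
  and stains) distributions, the same aggregation at which the real study
  reports the effect.
- The tangential arc's orientation (which ribbon end is position 0) is a
  convention; tangential maps are reproducible but their left/right
  orientation is not anatomically meaningful.
- Serial alignment is only defined up to the reference section's frame;
  absolute accuracy versus ground truth degrades as a slow random walk
  with distance from the reference when section shapes vary.
- The slice-correlation validation of the reconstructed volume is
  reported but not asserted: after reconstruction, resampling losses can
  put the weaker stain's corresponding-slice median inside the null's
  upper tail.
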