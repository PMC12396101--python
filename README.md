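# stainmap

Serial-section histology reconstruction and laminar profiling for
functionally defined cortical regions.

`stainmap` is for labs that localize regions of interest with fMRI (e.g.,
macaque face patches along the superior temporal sulcus) and then ask what
those regions look like histologically: is a patch darker in cytochrome
oxidase (CO) or myelin stain than its neighbors, in which cortical layers,
and how reliably can two patches be told apart? The package takes a stack
of alternating CO/myelin stained 2D sections, reconstructs a coherent 3D
stain volume, computes equi-volume cortical depth bins per section,
extracts per-ROI staining depth profiles, and quantifies between-ROI
discriminability. A synthetic phantom generator with planted laminar
profiles, misalignments and staining drift makes the entire pipeline
testable end to end without any data download.

## What it computes

- **Serial rigid co-registration**: two-stage (binary brain-shape, then
  mutual information on GM/WM label images) alignment of neighboring
  sections, composed serially from a middle reference; stacking with
  section-axis interpolation to isotropic voxels.
- **Intensity-drift correction**: a quadratic fit to per-section mean
  intensities, with each section shifted additively onto the fit
  (within-section contrast untouched).
- **Equi-volume depth bins**: K = 15 strata of equal tissue area between
  the pial surface and the GM/WM boundary, via distance-transform depth,
  gradient-streamline columns, and per-column cumulative-area inversion.
  On an annulus the bin boundaries reproduce the closed-form equal-area
  law `r_k = sqrt(r_out² − (k/K)(r_out² − r_in²))`.
- **Depth profiles and statistics**: per-section, per-bin mean darkness
  (`1 − raw/255`) inside each ROI; pooled-variance t-tests with
  Benjamini–Hochberg FDR; outer (bins 1–7) vs inner (bins 8–15) splits;
  tangential 2D maps with positional face-vs-non-face subtraction.
- **Bootstrap discriminability**: 10,000-iteration bootstrap of Cohen's d
  between paired ROIs, with two-sample KS tests comparing the d
  distributions across three contrasts — CO vs myelin, outer vs inner
  depths, individual vs probabilistic (atlas-like) ROI definitions.

## Worked example

```sh
python examples/03_laminar_profiles.py
```

builds a clean phantom section, computes the 15 equi-volume bins, and
extracts the CO depth profile of the planted "ML" patch:

```
per-bin GM areas (px): [365, 346, 364, 352, 351, 368, 349, 357, 358, 354, 358, 354, 358, 350, 362]
area CV: 1.7%  (equal-volume bins should be equal to within a few percent)
bin :     1     2     3     4     5     6     7     8     9    10    11    12    13    14    15
meas: 0.480 0.476 0.467 0.488 0.548 0.611 0.649 0.585 0.565 0.516 0.472 0.427 0.408 0.413 0.417
true: 0.481 0.483 0.491 0.510 0.546 0.595 0.641 0.580 0.561 0.515 0.466 0.430 0.411 0.403 0.401
Pearson r measured vs planted: 0.988
```

The measured 15-bin profile tracks the planted laminar function to
r = 0.988: the broad CO band rises to its peak at bin 7 and carries the
+0.08 darkness offset planted in the patch's outer layers (the drop
between bins 7 and 8 is the offset's edge), and the near-equal per-bin
areas show the equi-volume parcellation doing its job.
`examples/05_full_pipeline.py`
runs all eleven stages on a 30-section phantom and prints the
between-patch t-tests and the three bootstrap contrasts.

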