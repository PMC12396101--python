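"""Histology-volume to reference-volume alignment and ROI projection.

The reconstructed stain volume is aligned to the anatomical reference with
a mutual-information affine registration (SimpleITK), optionally refined
by a demons-style diffeomorphic displacement field. Alignment quality is
validated slice-by-slice: Pearson correlations of corresponding slices are
compared against a null distribution built from non-corresponding pairs.
ROIs defined in reference space are warped into histology space with
nearest-neighbor resampling, restricted to GM, and extended along full
cortical columns so every depth bin is covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .core import SegmentedSection
from .laminar import DepthField
from .registration import HistoVolume, dice_coefficient

logger = logging.getLogger(__name__)

dice = dice_coefficient  # canonical overlap metric, 2|A&B|/(|A|+|B|)


@dataclass
class VolumeTransform:
    """Mapping between reference and histology volume grids.

    ``forward`` maps reference grid points onto histology grid points (the
    convention produced by registering histology onto the reference).
    """

    forward: sitk.Transform
    direction: str = "reference->histology"
    displacement: np.ndarray | None = None   # optional nonlinear refinement
    converged: bool = True
    mean_r_before: float = float("nan")
    mean_r_after: float = float("nan")

    def affine_matrix(self) -> np.ndarray:
        """4x4 matrix of the affine part in (x, y, z) = (col, row, slice) order."""
        tf = self.forward
        if isinstance(tf, sitk.CompositeTransform):
            tf = tf.GetNthTransform(0)
        a = np.array(tf.GetMatrix()).reshape(3, 3)
        c = np.array(tf.GetCenter())
        t = np.array(tf.GetTranslation())
        out = np.eye(4)
        out[:3, :3] = a
        out[:3, 3] = c - a @ c + t
        return out

    def resample_into_histology(self, image: np.ndarray, histo_shape,
                                nearest: bool = False) -> np.ndarray:
        """Warp a reference-space image onto the histology grid."""
        img = sitk.GetImageFromArray(np.asarray(image, np.float32))
        ref = sitk.Image([int(s) for s in histo_shape[::-1]], sitk.sitkFloat32)
        interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
        # output (histology) points must be mapped into the input (reference)
        inv = self.forward.GetInverse()
        out = sitk.Resample(img, ref, inv, interp, 0.0)
        return sitk.GetArrayFromImage(out)

    def resample_into_reference(self, image: np.ndarray, ref_shape,
                                nearest: bool = False) -> np.ndarray:
        img = sitk.GetImageFromArray(np.asarray(image, np.float32))
        ref = sitk.Image([int(s) for s in ref_shape[::-1]], sitk.sitkFloat32)
        interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
        out = sitk.Resample(img, ref, self.forward, interp, 0.0)
        return sitk.GetArrayFromImage(out)

    def map_reference_points(self, points: np.ndarray) -> np.ndarray:
        """Map (slice, row, col) reference points to histology coordinates."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.array([self.forward.TransformPoint(tuple(p[::-1]))
                        for p in pts])
        return out[:, ::-1]


@dataclass
class AlignmentReport:
    """Slice-wise correlation validation of a volume alignment."""

    correlations: np.ndarray          # corresponding pairs, NaN if degenerate
    null_correlations: np.ndarray     # non-corresponding pairs
    mean_r: float
    excluded_slices: list[int] = field(default_factory=list)
    #: practical upper bound on attainable r (e.g. the slice correlation
    #: between two aligned acquisitions of the same reference); NaN when no
    #: repeated acquisition is available to estimate it
    ceiling: float = float("nan")

    @property
    def null_q95(self) -> float:
        return float(np.quantile(self.null_correlations, 0.95)) \
            if self.null_correlations.size else float("nan")


def _slice_corr(a: np.ndarray, b: np.ndarray) -> float:
    mask = (a != 0) & (b != 0)
    if mask.sum() < 10:
        return float("nan")
    av, bv = a[mask], b[mask]
    if av.std() == 0 or bv.std() == 0:
        return float("nan")
    return float(np.corrcoef(av, bv)[0, 1])


def validate_alignment(vol_a: np.ndarray, vol_b: np.ndarray, axis: int = 0,
                       null_cap: int = 10_000, seed: int = 0,
                       ceiling: float = float("nan")) -> AlignmentReport:
    """Correlate corresponding slices; null = non-corresponding pairs."""
    vol_a = np.asarray(vol_a, float)
    vol_b = np.asarray(vol_b, float)
    if vol_a.shape != vol_b.shape:
        raise ValueError("volumes must share a grid")
    if not 0 <= axis < vol_a.ndim:
        raise ValueError("axis out of range")
    a = np.moveaxis(vol_a, axis, 0)
    b = np.moveaxis(vol_b, axis, 0)
    n = a.shape[0]
    corr = np.array([_slice_corr(a[i], b[i]) for i in range(n)])
    excluded = [int(i) for i in np.flatnonzero(~np.isfinite(corr))]
    if excluded:
        logger.warning("excluding %d degenerate slice pairs", len(excluded))

    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    if len(pairs) > null_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=null_cap, replace=False)
        pairs = [pairs[k] for k in idx]
    null = np.array([_slice_corr(a[i], b[j]) for i, j in pairs])
    null = null[np.isfinite(null)]
    finite = corr[np.isfinite(corr)]
    return AlignmentReport(correlations=corr, null_correlations=null,
                           mean_r=float(finite.mean()) if finite.size else
                           float("nan"), excluded_slices=excluded,
                           ceiling=float(ceiling))


def align_volumes(histo: HistoVolume | np.ndarray, reference: np.ndarray,
                  nonlinear: bool = False, iterations=(80, 40, 20),
                  sampling_fraction: float = 1.0, sampling_seed: int = 1,
                  demons_iterations: int = 20) -> VolumeTransform:
    """Affine (then optional demons) alignment of histology to reference.

    The histology volume is the moving image; the returned transform maps
    reference grid points onto histology grid points, which is the
    direction needed to project reference-space ROIs into section space.
    """
    moving = histo.data if isinstance(histo, HistoVolume) else np.asarray(histo)
    fixed = np.asarray(reference, float)
    if moving.ndim != 3 or fixed.ndim != 3:
        raise ValueError("expected 3D volumes")
    if min(moving.shape) < 4 or min(fixed.shape) < 4:
        raise ValueError("degenerate overlap between volumes")

    f_img = sitk.GetImageFromArray(np.asarray(fixed, np.float32))
    m_img = sitk.GetImageFromArray(np.asarray(moving, np.float32))

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    if sampling_fraction >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling
    else:  # regular grid subsampling with a fixed seed: still deterministic
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(float(sampling_fraction),
                                        int(sampling_seed))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescentLineSearch(
        learningRate=1.0, numberOfIterations=int(max(iterations)),
        convergenceMinimumValue=1e-6, convergenceWindowSize=10)
    reg.SetOptimizerScalesFromPhysicalShift()
    levels = len(iterations)
    reg.SetShrinkFactorsPerLevel([2 ** (levels - 1 - i) for i in range(levels)])
    reg.SetSmoothingSigmasPerLevel(
        [max(levels - 1 - i, 0) for i in range(levels)])
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        affine = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # e.g. optimizer drove images apart
        logger.warning("affine registration failed to converge: %s", exc)
        tf = VolumeTransform(forward=initial, converged=False)
        return tf

    tf = VolumeTransform(forward=affine)
    before = validate_alignment(fixed, _resample_like(m_img, f_img,
                                                      sitk.Transform(3,
                                                                     sitk.sitkIdentity)))
    after = validate_alignment(fixed, _resample_like(m_img, f_img, affine))
    tf.mean_r_before = before.mean_r
    tf.mean_r_after = after.mean_r
    tf.converged = bool(np.isnan(before.mean_r)
                        or after.mean_r >= before.mean_r - 0.005
                        ) and after.mean_r > 0.2
    if not tf.converged:
        logger.warning("volume alignment flagged: mean r %.3f -> %.3f",
                       before.mean_r, after.mean_r)

    if nonlinear and tf.converged:
        moved = sitk.Resample(m_img, f_img, affine, sitk.sitkLinear, 0.0)
        matched = sitk.HistogramMatching(moved, f_img)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(demons_iterations))
        demons.SetStandardDeviations(1.5)
        disp = demons.Execute(f_img, matched)
        tf.displacement = sitk.GetArrayFromImage(disp)
        composite = sitk.CompositeTransform(3)
        composite.AddTransform(sitk.DisplacementFieldTransform(disp))
        composite.AddTransform(affine)
        tf.forward = composite
    return tf


def _resample_like(moving: sitk.Image, fixed: sitk.Image,
                   transform: sitk.Transform) -> np.ndarray:
    return sitk.GetArrayFromImage(
        sitk.Resample(moving, fixed, transform, sitk.sitkLinear, 0.0))


def extend_roi_across_depth(roi: np.ndarray, depth_field: DepthField
                            ) -> np.ndarray:
    """Extend an ROI perpendicularly so it spans the full cortical depth.

    All GM pixels whose tangential arc coordinate falls inside the ROI's
    arc interval are included, at pixel resolution (so sub-column ROI
    displacements are preserved). Candidate pixels are restricted to the
    connected patches that actually touch the input ROI, which keeps the
    interval from bleeding into unrelated GM components. Idempotent.
    """
    from scipy import ndimage as _ndi

    roi = np.asarray(roi, bool) & depth_field.gm_mask
    if not roi.any():
        return roi
    arcs = depth_field.arc[roi]
    lo, hi = float(np.nanmin(arcs)), float(np.nanmax(arcs))
    cand = depth_field.gm_mask & (depth_field.arc >= lo) \
        & (depth_field.arc <= hi)
    lab, n = _ndi.label(cand, _ndi.generate_binary_structure(2, 2))
    keep = np.unique(lab[roi])
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def project_roi(roi_volume: np.ndarray, transform: VolumeTransform,
                segmentations: list[SegmentedSection],
                depth_fields: list[DepthField],
                section_slices: dict[int, int],
                histo_shape=None) -> dict[int, np.ndarray]:
    """Project a reference-space ROI volume into per-section GM masks.

    The ROI is warped into the histology grid (nearest neighbor), sliced at
    each original section's position, restricted to GM, and extended along
    each touched cortical column to cover the full depth range.
    """
    if histo_shape is None:
        histo_shape = (max(section_slices.values()) + 1,
                       *segmentations[0].labels.shape)
    warped = transform.resample_into_histology(
        np.asarray(roi_volume, float), histo_shape, nearest=True) > 0.5
    out: dict[int, np.ndarray] = {}
    any_nonempty = False
    for i, (seg, df) in enumerate(zip(segmentations, depth_fields)):
        j = section_slices.get(i)
        if j is None or j >= warped.shape[0]:
            continue
        mask2d = warped[j] & seg.gm_mask
        if mask2d.any():
            any_nonempty = True
            out[i] = extend_roi_across_depth(mask2d, df)
        else:
            out[i] = np.zeros_like(seg.gm_mask)
    if not any_nonempty:
        raise ValueError("warped ROI is empty (or entirely off GM) "
                         "in all sections")
    return out
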