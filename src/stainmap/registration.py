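"""Two-stage serial rigid co-registration, drift correction, and stacking.

Stage 1 registers binary brain masks (mean squares after light Gaussian
smoothing; centroid-initialized, coarse rotation scan then Powell
refinement). Stage 2 refines on the 0/127/255 GM/WM label images by
maximizing a 32-bin joint-histogram mutual information, seeded with the
stage-1 solution. Both stages are fully deterministic: no stochastic
sampling is used anywhere.

Sections are aligned serially ascending and descending from a middle
reference section, each section registered to its already-aligned
neighbor, and both stages' transforms are finally applied to the original
stain images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import SegmentedSection, StainSection
from .segmentation import boundary_masks, segment_section
from .transforms import RigidTransform2D


class SerialAlignmentError(RuntimeError):
    """A pairwise registration failed; carries the failing pair index."""

    def __init__(self, moving_index: int, fixed_index: int, message: str = ""):
        self.moving_index = moving_index
        self.fixed_index = fixed_index
        super().__init__(
            f"registration of section {moving_index} to {fixed_index} failed"
            + (f": {message}" if message else ""))


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    metric: float
    converged: bool


def _centroid(mask: np.ndarray) -> np.ndarray:
    return np.asarray(ndimage.center_of_mass(np.asarray(mask, float)))


def _param_transform(theta: float, dr: float, dc: float,
                     c_mov: np.ndarray, c_fix: np.ndarray) -> RigidTransform2D:
    """Rotation ``theta`` about the moving centroid, then a translation that
    carries the moving centroid onto the fixed centroid plus (dr, dc)."""
    t = (float(c_fix[0] - c_mov[0] + dr), float(c_fix[1] - c_mov[1] + dc))
    return RigidTransform2D(float(theta), t, center=(float(c_mov[0]), float(c_mov[1])))


def _params_from_transform(tf: RigidTransform2D, c_mov: np.ndarray,
                           c_fix: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`_param_transform` for an arbitrary rigid transform."""
    d = tf.offset - (c_fix - tf.matrix @ c_mov)
    return float(tf.rotation_deg), float(d[0]), float(d[1])


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks empty")
    return 2.0 * np.count_nonzero(a & b) / (na + nb)


def register_pair_binary(moving: np.ndarray, fixed: np.ndarray,
                         max_rotation: float = 10.0,
                         smooth_sigma: float = 1.0) -> RegistrationResult:
    """Rigid registration of two binary brain masks (mean squares)."""
    moving = np.asarray(moving, bool)
    fixed = np.asarray(fixed, bool)
    if not moving.any() or not fixed.any():
        raise ValueError("empty mask")
    mov = ndimage.gaussian_filter(moving.astype(float), smooth_sigma)
    fix = ndimage.gaussian_filter(fixed.astype(float), smooth_sigma)
    c_mov, c_fix = _centroid(moving), _centroid(fixed)

    def objective(p):
        tf = _param_transform(p[0], p[1], p[2], c_mov, c_fix)
        moved = tf.apply_to_image(mov, order=1)
        return float(np.mean((moved - fix) ** 2))

    angles = np.arange(-max_rotation, max_rotation + 0.5, 1.0)
    coarse = [objective((a, 0.0, 0.0)) for a in angles]
    best0 = angles[int(np.argmin(coarse))]
    res = optimize.minimize(objective, x0=[best0, 0.0, 0.0], method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-9, "maxiter": 200})
    tf = _param_transform(res.x[0], res.x[1], res.x[2], c_mov, c_fix)
    moved_bin = tf.apply_to_image(moving, order=0)
    try:
        overlap = dice_coefficient(moved_bin, fixed)
    except ValueError:
        overlap = 0.0
    return RegistrationResult(transform=tf, metric=float(res.fun),
                              converged=overlap >= 0.5)


def _mutual_information(a: np.ndarray, b: np.ndarray, support: np.ndarray,
                        bins: int = 32) -> float:
    h, _, _ = np.histogram2d(a[support], b[support], bins=bins,
                             range=[[0, 255], [0, 255]])
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def register_pair_multimodal(moving: SegmentedSection, fixed: SegmentedSection,
                             initial: RigidTransform2D | None = None,
                             smooth_sigma: float = 1.0) -> RegistrationResult:
    """MI refinement on label images, seeded by ``initial`` (or centroids).

    Label images are lightly smoothed before the metric: on categorical
    0/127/255 images the MI optimum can sit a fraction of a pixel off due
    to boundary rasterization, which the smoothing removes.

    If either section has empty GM there is no shared laminar structure to
    drive the metric; a flagged (non-converged) result is returned.
    """
    mov_lab = np.asarray(moving.labels, float)
    fix_lab = np.asarray(fixed.labels, float)
    mov_brain = mov_lab > 0
    fix_brain = fix_lab > 0
    if smooth_sigma > 0:
        mov_lab = ndimage.gaussian_filter(mov_lab, smooth_sigma)
        fix_lab = ndimage.gaussian_filter(fix_lab, smooth_sigma)
    if not mov_brain.any() or not fix_brain.any():
        raise ValueError("empty section")
    if not moving.gm_mask.any() or not fixed.gm_mask.any():
        tf = initial or RigidTransform2D.identity()
        return RegistrationResult(transform=tf, metric=float("nan"),
                                  converged=False)
    c_mov, c_fix = _centroid(mov_brain), _centroid(fix_brain)
    if initial is None:
        p0 = (0.0, 0.0, 0.0)
    else:
        p0 = _params_from_transform(initial, c_mov, c_fix)
    fix_support = fix_brain

    def objective(p):
        tf = _param_transform(p[0], p[1], p[2], c_mov, c_fix)
        moved = tf.apply_to_image(mov_lab, order=1)
        support = fix_support | (moved > 0)
        return -_mutual_information(moved, fix_lab, support)

    res = optimize.minimize(objective, x0=list(p0), method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-10, "maxiter": 200})
    x = res.x if res.fun <= objective(p0) else np.asarray(p0)
    tf = _param_transform(x[0], x[1], x[2], c_mov, c_fix)
    moved_gm = tf.apply_to_image(moving.gm_mask, order=0)
    try:
        gm_overlap = dice_coefficient(moved_gm, fixed.gm_mask)
    except ValueError:
        gm_overlap = 0.0
    return RegistrationResult(transform=tf, metric=float(res.fun),
                              converged=gm_overlap >= 0.5)


@dataclass
class SerialAlignment:
    """Result of two-stage serial alignment of a section stack."""

    transforms: list[RigidTransform2D]          # composite, per section
    stage1_transforms: list[RigidTransform2D]
    aligned_images: list[np.ndarray]            # float intensities, aligned frame
    aligned_segmentations: list[SegmentedSection]
    reference_index: int
    metrics: list[float] = field(default_factory=list)


def _serial_order(n: int, ref: int):
    """Visit order away from the reference with the neighbor toward it."""
    for i in range(ref - 1, -1, -1):
        yield i, i + 1
    for i in range(ref + 1, n):
        yield i, i - 1


def serial_align(sections: list[StainSection],
                 reference_index: int | None = None,
                 segmentations: list[SegmentedSection] | None = None,
                 max_rotation: float = 10.0) -> SerialAlignment:
    """Two-stage serial rigid alignment of an (interleaved-stain) stack."""
    n = len(sections)
    if n < 2:
        raise ValueError("need at least 2 sections")
    ref = n // 2 if reference_index is None else reference_index
    if not 0 <= ref < n:
        raise ValueError("reference_index out of range")
    if segmentations is None:
        segmentations = [segment_section(s) for s in sections]
    brains = [s.labels > 0 for s in segmentations]

    # Both stages estimate each *raw* neighbor pair (binary shape first,
    # MI label refinement seeded by it), and per-section transforms are
    # obtained by composing the pairwise results toward the reference.
    # Registering raw pairs keeps resampling out of the estimation, so the
    # only chain error is the (small, unbiased) pairwise residual.
    t1: list[RigidTransform2D | None] = [None] * n
    t2: list[RigidTransform2D | None] = [None] * n
    t1[ref] = RigidTransform2D.identity()
    t2[ref] = RigidTransform2D.identity()
    metrics = [0.0] * n
    for i, nb in _serial_order(n, ref):
        res1 = register_pair_binary(brains[i], brains[nb],
                                    max_rotation=max_rotation)
        if not res1.converged:
            raise SerialAlignmentError(i, nb, "binary stage did not converge")
        res2 = register_pair_multimodal(segmentations[i], segmentations[nb],
                                        initial=res1.transform)
        if not res2.converged:
            raise SerialAlignmentError(i, nb, "multimodal stage did not converge")
        t1[i] = t1[nb].compose(res1.transform)
        t2[i] = t2[nb].compose(res2.transform)
        metrics[i] = res2.metric

    aligned_images = []
    aligned_segs = []
    for i, sec in enumerate(sections):
        img = t2[i].apply_to_image(np.asarray(sec.image, float), order=1)
        if t2[i].is_identity():
            img = np.asarray(sec.image, float)  # reference stays bit-for-bit
        labels = np.asarray(t2[i].apply_to_image(segmentations[i].labels,
                                                 order=0)).astype(np.uint8)
        outer, inner = boundary_masks(labels)
        aligned_images.append(img)
        aligned_segs.append(SegmentedSection(labels=labels, outer_boundary=outer,
                                             inner_boundary=inner, index=i,
                                             stain=sec.stain))
    return SerialAlignment(transforms=list(t2), stage1_transforms=list(t1),
                           aligned_images=aligned_images,
                           aligned_segmentations=aligned_segs,
                           reference_index=ref, metrics=metrics)


@dataclass
class DriftModel:
    """Quadratic fit to per-section mean intensities of one stain."""

    coefficients: np.ndarray        # np.polyfit order: [a, b, c]
    section_indices: np.ndarray
    raw_means: np.ndarray
    fitted_means: np.ndarray
    residuals: np.ndarray           # raw - fit; the removed deviations
    clipped_fraction: float


def correct_intensity_drift(images: list[np.ndarray],
                            masks: list[np.ndarray] | None = None,
                            section_indices: list[int] | None = None,
                            value_range: tuple[float, float] = (0.0, 255.0)
                            ) -> tuple[list[np.ndarray], DriftModel]:
    """Remove per-section mean-intensity deviations from a quadratic trend.

    Fits mean brain-pixel intensity vs section index with a least-squares
    quadratic and shifts each section additively by (fit - mean), so the
    corrected means lie exactly on the fit and within-section contrasts are
    untouched. Intensities are clipped to ``value_range`` afterwards, with
    the clipped pixel fraction reported.
    """
    if len(images) < 3:
        raise ValueError("quadratic drift fit needs at least 3 sections")
    if masks is None:
        masks = [np.asarray(im) > 0 for im in images]
    x = np.asarray(section_indices if section_indices is not None
                   else range(len(images)), float)
    means = np.array([float(np.mean(np.asarray(im, float)[m]))
                      for im, m in zip(images, masks)])
    coeffs = np.polyfit(x, means, 2)
    fitted = np.polyval(coeffs, x)

    corrected = []
    clipped = 0
    total = 0
    for im, m, mu, fit in zip(images, masks, means, fitted):
        out = np.asarray(im, float).copy()
        out[m] += fit - mu
        n_clip = int(np.count_nonzero((out[m] < value_range[0])
                                      | (out[m] > value_range[1])))
        clipped += n_clip
        total += int(m.sum())
        out[m] = np.clip(out[m], *value_range)
        corrected.append(out)
    model = DriftModel(coefficients=coeffs, section_indices=x, raw_means=means,
                       fitted_means=fitted, residuals=means - fitted,
                       clipped_fraction=clipped / max(total, 1))
    return corrected, model


@dataclass
class HistoVolume:
    """Reconstructed 3D stain volume with isotropic voxels."""

    data: np.ndarray                  # (slice, row, col)
    pixel_size_um: float
    section_spacing_um: float
    stain: str
    provenance: list[str]             # per slice: "section:<i>" or "interpolated"
    section_slices: dict[int, int]    # stack position -> slice index

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def stack_to_volume(images: list[np.ndarray], spacing_um: float,
                    pixel_size_um: float, stain: str = "co") -> HistoVolume:
    """Stack aligned sections and interpolate the section axis to isotropy.

    The section axis is linearly interpolated so that the voxel spacing
    along it equals the in-plane pixel size (e.g. 50 um sections at 25 um
    pixels give one interpolated slice between each pair of originals).
    """
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("sections must share one image shape")
    stack = np.asarray(images, float)
    n = stack.shape[0]
    if n == 1:
        return HistoVolume(stack.copy(), pixel_size_um, spacing_um, stain,
                           ["section:0"], {0: 0})
    factor = spacing_um / pixel_size_um
    n_out = int(round((n - 1) * factor)) + 1
    z = np.arange(n_out) / factor          # in units of section index
    lo = np.clip(np.floor(z).astype(int), 0, n - 1)
    hi = np.clip(lo + 1, 0, n - 1)
    w = (z - lo)[:, None, None]
    data = (1 - w) * stack[lo] + w * stack[hi]
    provenance = []
    section_slices = {}
    for j, zj in enumerate(z):
        i = int(round(zj))
        if abs(zj - i) < 1e-9:
            provenance.append(f"section:{i}")
            section_slices[i] = j
        else:
            provenance.append("interpolated")
    return HistoVolume(data, pixel_size_um, spacing_um, stain, provenance,
                       section_slices)
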