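"""Synthetic serial-section phantom with known ground truth.

The phantom emulates alternating CO / myelin stained 50-um sections through
a folded cortical ribbon: a circular-arc gray-matter band over a white
matter core, with depth-dependent staining planted per ROI, per-section
rigid misalignment, per-section mean-intensity drift (smooth quadratic
trend plus alternating high-frequency deviations), pixel noise, and
spatially jittered ROI copies standing in for probabilistic atlas
definitions. Every quantity the reconstruction and profiling pipeline
estimates is available here as ground truth.

Laminar profiles are planted as functions of *equi-volume* depth
``v = (r_out^2 - r^2) / (r_out^2 - r_in^2)`` (the coordinate the depth
analysis measures), so a band planted at depths 0.45-0.55 lands in depth
bins 7-8 of a 15-bin parcellation. The analytic annulus fixture
(:func:`render_annulus_section`) instead takes its profile in the radial
fraction ``(r_out - r) / (r_out - r_in)``, which is the natural coordinate
for testing the equal-area law in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import (LABEL_GM, LABEL_WM, STAIN_CO, STAIN_MYELIN,
                   SegmentedSection, StainSection)
from .segmentation import boundary_masks
from .transforms import RigidTransform2D

ProfileFn = Callable[[np.ndarray], np.ndarray]

#: darkness range kept clear of 0/255 so drift offsets never clip
_DARKNESS_LO = 0.08
_DARKNESS_HI = 0.90


def _quantize(d: np.ndarray | float) -> np.ndarray | float:
    """Snap darkness to the 1/255 grid of the 8-bit export."""
    return np.round(np.asarray(d, float) * 255.0) / 255.0


@dataclass
class PhantomConfig:
    """Data-generating parameters for one synthetic hemisphere."""

    n_sections: int = 30
    image_shape: tuple[int, int] = (192, 192)
    section_spacing_um: float = 50.0
    pixel_size_um: float = 25.0
    # ribbon geometry: circular arc of GM over a WM disk
    center: tuple[float, float] = (96.0, 96.0)
    r_in: float = 42.0
    r_out: float = 70.0
    arc_start_deg: float = -10.0
    arc_end_deg: float = 190.0
    shrink_per_section: float = 0.002    # radial scale loss per section from middle
    span_shrink_deg_per_section: float = 0.8   # arc-span loss away from middle
    span_wiggle_deg: float = 1.0         # random per-section arc-span variation
    radius_wiggle_px: float = 0.3        # random per-section outer-radius variation
    tangential_gradient: float = 0.0     # darkness slope along the ribbon arc
    # smooth per-section tissue texture, visible in the stains and in the
    # reference volume alike; kept small enough that GM/WM intensity classes
    # stay separable for the thresholding stage
    texture_amplitude: float = 0.03
    texture_smooth_px: float = 1.5
    # staining
    laminar_profiles: dict[str, dict[str, ProfileFn]] = field(default_factory=dict)
    wm_darkness: dict[str, float] = field(
        default_factory=lambda: {STAIN_CO: 0.15, STAIN_MYELIN: 0.84})
    # ROIs: normalized arc-length spans (disjoint) and inclusive section ranges
    roi_spans: dict[str, tuple[float, float]] = field(default_factory=dict)
    roi_section_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    # nuisance processes
    misalignment_amplitude: tuple[float, float] = (4.0, 8.0)   # (deg, px)
    drift_quad: tuple[float, float, float] = (0.0, 0.0, 0.0)   # darkness units
    drift_hf_amplitude: float = 0.0
    noise_sd: float = 0.01
    # probabilistic-ROI emulation
    roi_jitter_px: float = 16.0
    roi_dilation_px: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sections < 3:
            raise ValueError("n_sections must be >= 3")
        if not (0 < self.r_in < self.r_out):
            raise ValueError("need 0 < r_in < r_out")
        max_rot, max_tr = self.misalignment_amplitude
        margin = self.r_out + max_tr + 2.0
        cy, cx = self.center
        h, w = self.image_shape
        if not (margin <= cy <= h - margin and margin <= cx <= w - margin):
            raise ValueError("ribbon (plus misalignment) does not fit in the image")
        span0 = self.arc_end_deg - self.arc_start_deg
        mid = self.n_sections // 2
        min_frac = (span0 - self.span_wiggle_deg
                    - self.span_shrink_deg_per_section
                    * max(mid, self.n_sections - 1 - mid)) / span0
        spans = sorted(self.roi_spans.values())
        for (a0, a1) in spans:
            if not (0.0 <= a0 < a1 <= 1.0):
                raise ValueError("ROI span outside ribbon arc-length [0, 1]")
            if a1 > min_frac:
                raise ValueError(
                    "ROI span extends beyond the shortest section's ribbon")
        for (_, a1), (b0, _) in zip(spans[:-1], spans[1:]):
            if b0 < a1:
                raise ValueError("ROI spans must be pairwise disjoint")
        for stain, profs in self.laminar_profiles.items():
            v = np.linspace(0, 1, 64)
            for name, fn in profs.items():
                vals = np.asarray(fn(v), float)
                if vals.min() < 0 or vals.max() > 1:
                    raise ValueError(f"profile {stain}/{name} leaves [0, 1]")


def default_config(**overrides) -> PhantomConfig:
    """Study-scale phantom: 30 alternating sections, three face-patch ROIs.

    The planted contrasts mirror the study's direction of effects: the ML
    patch is darker than the rest of the ribbon by +0.08 in CO and +0.02 in
    myelin, confined to the outer depth bins (equi-volume depth < 7/15).
    """
    outer = 7.0 / 15.0

    def co_base(v):
        v = np.asarray(v, float)
        return 0.40 + 0.18 * np.exp(-(((v - 0.50) / 0.20) ** 2))

    def myelin_base(v):
        v = np.asarray(v, float)
        return 0.25 + 0.30 * v

    def with_outer_offset(base, delta):
        return lambda v: np.clip(base(v) + delta * (np.asarray(v, float) < outer),
                                 0.0, 1.0)

    profiles = {
        STAIN_CO: {
            "base": co_base,
            "ML": with_outer_offset(co_base, 0.08),
            "AL": co_base,
            "AFAD": co_base,
        },
        STAIN_MYELIN: {
            "base": myelin_base,
            "ML": with_outer_offset(myelin_base, 0.02),
            "AL": myelin_base,
            "AFAD": myelin_base,
        },
    }
    n = overrides.get("n_sections", 30)
    cfg = PhantomConfig(
        laminar_profiles=profiles,
        roi_spans={"ML": (0.16, 0.32), "AL": (0.45, 0.61), "AFAD": (0.66, 0.82)},
        roi_section_ranges={"ML": (1, n - 5), "AL": (3, n - 2), "AFAD": (2, n - 4)},
        drift_quad=(-1.2e-4, 3.5e-3, 0.01),
        drift_hf_amplitude=0.015,
        misalignment_amplitude=(4.0, 8.0),
        noise_sd=0.01,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class PhantomDataset:
    """Raw sections plus every ground-truth quantity used by the tests."""

    sections: list[StainSection]                 # raw: misaligned + drifted
    clean_sections: list[np.ndarray]             # darkness, clean frame
    clean_segmentations: list[SegmentedSection]  # truth labels, clean frame
    truth_transforms: list[RigidTransform2D]     # clean -> raw frame
    truth_drift: np.ndarray                      # per-section darkness offset
    truth_profiles: dict[str, dict[str, ProfileFn]]
    roi_masks: dict[str, list[np.ndarray]]       # truth, clean frame, per section
    roi_masks_jittered: dict[str, list[np.ndarray]]
    reference_volume: np.ndarray                 # smoothed stand-in for the MRI
    config: PhantomConfig

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def gm_mask(self, i: int) -> np.ndarray:
        return self.clean_segmentations[i].gm_mask


def _polar(shape, center):
    rows, cols = np.indices(shape)
    dy = rows - center[0]
    dx = cols - center[1]
    r = np.hypot(dy, dx)
    theta = np.rad2deg(np.arctan2(dy, dx))
    return r, theta, dy, dx


def _section_geometry(cfg: PhantomConfig, i: int, rng: np.random.Generator):
    """Per-section geometry draws (shared by clean and raw renders)."""
    mid = cfg.n_sections // 2
    scale = 1.0 - cfg.shrink_per_section * abs(i - mid)
    r_in = cfg.r_in * scale
    r_out = cfg.r_out * scale + rng.uniform(-cfg.radius_wiggle_px,
                                            cfg.radius_wiggle_px)
    span0 = cfg.arc_end_deg - cfg.arc_start_deg
    span_i = span0 - cfg.span_shrink_deg_per_section * abs(i - mid) \
        + rng.uniform(-cfg.span_wiggle_deg, cfg.span_wiggle_deg)
    stain = STAIN_CO if i % 2 == 0 else STAIN_MYELIN
    return {"r_in": r_in, "r_out": r_out, "span": span_i, "stain": stain}


def _render_frame(cfg: PhantomConfig, i: int, geom: dict,
                  texture: np.ndarray, noise: np.ndarray,
                  transform: RigidTransform2D | None = None):
    """Render section i analytically in the clean or the misaligned frame.

    The class geometry (GM arc, WM core, brainstem stub) is evaluated in
    closed form in the target frame, so raw sections have boundaries as
    sharp as clean ones; only the smooth texture and noise fields are
    supplied pre-warped by the caller.
    """
    if transform is None or transform.is_identity():
        center = np.asarray(cfg.center, float)
        rot = 0.0
    else:
        center = transform.apply_to_points(np.asarray([cfg.center]))[0]
        rot = transform.rotation_deg
    rows, cols = np.indices(cfg.image_shape)
    dy = rows - center[0]
    dx = cols - center[1]
    if rot != 0.0:
        th = np.deg2rad(rot)
        dyr = np.cos(th) * dy + np.sin(th) * dx
        dxr = -np.sin(th) * dy + np.cos(th) * dx
    else:
        dyr, dxr = dy, dx
    r = np.hypot(dyr, dxr)
    theta = np.rad2deg(np.arctan2(dyr, dxr))

    r_in, r_out, span_i = geom["r_in"], geom["r_out"], geom["span"]
    stain = geom["stain"]
    span0 = cfg.arc_end_deg - cfg.arc_start_deg
    # arc fraction is anchored to the full (middle-section) span so ROI
    # angle intervals stay fixed while the ribbon shortens away from middle
    arc_frac = ((theta - cfg.arc_start_deg) % 360.0) / span0
    in_arc = arc_frac <= span_i / span0

    # WM core plus a "brainstem" stub on the free side of the ribbon: the
    # stub breaks the near-circular outline so rigid rotation is anchored
    # even when the arc span varies from section to section
    stub = (np.abs(dxr) <= 12) & (dyr <= 0) & (r <= 0.97 * r_out)
    wm = (r < r_in) | stub
    gm = in_arc & (r >= r_in) & (r < r_out) & ~stub
    v = np.clip((r_out ** 2 - r ** 2) / (r_out ** 2 - r_in ** 2), 0.0, 1.0)

    profs = cfg.laminar_profiles[stain]
    darkness = np.zeros(cfg.image_shape)
    darkness[wm] = cfg.wm_darkness[stain]
    darkness[gm] = np.asarray(profs["base"](v[gm]), float)

    rois: dict[str, np.ndarray] = {}
    for name, (a0, a1) in cfg.roi_spans.items():
        lo, hi = cfg.roi_section_ranges.get(name, (0, cfg.n_sections - 1))
        mask = gm & (arc_frac >= a0) & (arc_frac <= a1) if lo <= i <= hi else \
            np.zeros(cfg.image_shape, bool)
        rois[name] = mask
        if mask.any() and name in profs:
            darkness[mask] = np.asarray(profs[name](v[mask]), float)

    brain = wm | gm
    if cfg.tangential_gradient != 0.0:
        darkness[gm] += cfg.tangential_gradient * arc_frac[gm]
    if cfg.texture_amplitude > 0:
        # texture is a within-tissue property: taper it to zero at class
        # boundaries so it cannot blur the GM/WM/background transitions.
        # The sign is chosen per stain so each stain correlates positively
        # with the T1-like reference under its own contrast polarity
        # (CO compared as intensity, myelin as darkness).
        taper = np.zeros(cfg.image_shape)
        for cls in (gm, wm):
            d = ndimage.distance_transform_edt(cls)
            taper[cls] = np.clip(d[cls] / 2.0, 0.0, 1.0)
        sign = 1.0 if stain == STAIN_MYELIN else -1.0
        darkness[brain] += (sign * cfg.texture_amplitude
                            * (texture * taper)[brain])
    if cfg.noise_sd > 0:
        darkness[brain] += noise[brain]
    darkness = np.where(brain, np.clip(darkness, _DARKNESS_LO, _DARKNESS_HI),
                        0.0)
    darkness = _quantize(darkness)

    labels = np.zeros(cfg.image_shape, np.uint8)
    labels[gm] = LABEL_GM
    labels[wm] = LABEL_WM
    outer, inner = boundary_masks(labels)
    seg = SegmentedSection(labels=labels, outer_boundary=outer,
                           inner_boundary=inner, index=i, stain=stain)
    return darkness, seg, rois


def _export_uint8(darkness: np.ndarray, brain: np.ndarray) -> np.ndarray:
    """8-bit raw image: background 0, brain 255*(1 - darkness) clipped to >= 1."""
    img = np.rint(255.0 * (1.0 - darkness)).astype(int)
    img = np.clip(img, 1, 255)
    img[~brain] = 0
    return img.astype(np.uint8)


def generate_phantom(config: PhantomConfig) -> PhantomDataset:
    """Generate a full phantom dataset (deterministic in ``config.seed``).

    Raw sections are the clean renders composed with the per-section truth
    rigid transform, then shifted by the per-section drift offset. The
    middle (reference) section keeps the identity transform so the serially
    aligned stack reconstructs the clean ground-truth frame.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mid = cfg.n_sections // 2
    max_rot, max_tr = cfg.misalignment_amplitude
    a, b, c = cfg.drift_quad

    sections: list[StainSection] = []
    clean: list[np.ndarray] = []
    segs: list[SegmentedSection] = []
    transforms: list[RigidTransform2D] = []
    drift = np.zeros(cfg.n_sections)
    roi_masks: dict[str, list[np.ndarray]] = {k: [] for k in cfg.roi_spans}

    textures: list[np.ndarray] = []
    for i in range(cfg.n_sections):
        geom = _section_geometry(cfg, i, rng)
        if cfg.texture_amplitude > 0:
            texture = ndimage.gaussian_filter(
                rng.standard_normal(cfg.image_shape), cfg.texture_smooth_px)
            texture /= max(texture.std(), 1e-12)
        else:
            texture = np.zeros(cfg.image_shape)
        noise = rng.normal(0.0, cfg.noise_sd, cfg.image_shape) \
            if cfg.noise_sd > 0 else np.zeros(cfg.image_shape)

        darkness, seg, rois = _render_frame(cfg, i, geom, texture, noise)
        clean.append(darkness)
        segs.append(seg)
        textures.append(texture)
        for name in roi_masks:
            roi_masks[name].append(rois[name])

        if i == mid or (max_rot == 0 and max_tr == 0):
            tf = RigidTransform2D.identity()
        else:
            rot = rng.uniform(-max_rot, max_rot)
            tr = tuple(rng.uniform(-max_tr, max_tr, 2))
            tf = RigidTransform2D(rot, tr, center=cfg.center)
        transforms.append(tf)

        hf = cfg.drift_hf_amplitude * ((-1.0) ** i) * rng.uniform(0.5, 1.0)
        off = float(_quantize(a * i * i + b * i + c + hf))
        drift[i] = off

        # raw section: geometry re-rendered analytically in the misaligned
        # frame (sharp class boundaries); smooth fields warped alongside
        if tf.is_identity():
            raw_dark, raw_seg = darkness.copy(), seg
        else:
            raw_dark, raw_seg, _ = _render_frame(
                cfg, i, geom, tf.apply_to_image(texture, order=1),
                tf.apply_to_image(noise, order=1), transform=tf)
        raw_brain = raw_seg.labels > 0
        if (raw_brain[0].any() or raw_brain[-1].any()
                or raw_brain[:, 0].any() or raw_brain[:, -1].any()):
            raise ValueError(f"misalignment pushes section {i} out of frame")
        raw_dark = np.where(raw_brain,
                            np.clip(raw_dark + off, 1.0 / 255, 254.0 / 255),
                            0.0)
        sections.append(StainSection(image=_export_uint8(raw_dark, raw_brain),
                                     stain=geom["stain"], index=i,
                                     pixel_size_um=cfg.pixel_size_um))

    # probabilistic-atlas emulation: one displacement per ROI per hemisphere,
    # directed along the ribbon tangent (localization error runs along the
    # cortical sheet; radial error is nullified by the depth extension)
    jitter_seed = int(rng.integers(0, 2 ** 31 - 1))
    span0 = cfg.arc_end_deg - cfg.arc_start_deg
    jittered = {}
    for k, name in enumerate(sorted(cfg.roi_spans)):
        a0, a1 = cfg.roi_spans[name]
        theta_c = np.deg2rad(cfg.arc_start_deg + 0.5 * (a0 + a1) * span0)
        tangent = (np.cos(theta_c), -np.sin(theta_c))   # (drow, dcol)
        jittered[name] = [
            perturb_roi(m, cfg.roi_jitter_px, cfg.roi_dilation_px,
                        seed=jitter_seed + k, gm=seg_i.gm_mask,
                        direction=tangent)
            if m.any() else m.copy()
            for m, seg_i in zip(roi_masks[name], segs)]

    # structural stand-in for the anatomical MRI: bright WM, mid-gray
    # cortex (smoothed), plus the same per-section tissue texture the
    # stains carry at full resolution (the MRI sees the same tissue)
    struct = np.stack([0.35 * s.gm_mask + 0.9 * s.wm_mask for s in segs])
    reference = ndimage.gaussian_filter(struct, sigma=(0.4, 1.0, 1.0))
    reference += np.stack([cfg.texture_amplitude * t * (s.labels > 0)
                           for s, t in zip(segs, textures)])
    return PhantomDataset(sections=sections, clean_sections=clean,
                          clean_segmentations=segs, truth_transforms=transforms,
                          truth_drift=drift, truth_profiles=cfg.laminar_profiles,
                          roi_masks=roi_masks, roi_masks_jittered=jittered,
                          reference_volume=reference, config=cfg)


def render_annulus_section(r_in: float, r_out: float, profile: ProfileFn,
                           image_shape: tuple[int, int] = (192, 192),
                           stain: str = STAIN_CO, index: int = 0,
                           wm_darkness: float = 0.15
                           ) -> tuple[StainSection, SegmentedSection]:
    """Analytic fixture: full GM annulus between ``r_in`` and ``r_out``.

    Darkness at radius r is ``profile((r_out - r) / (r_out - r_in))`` (the
    radial fraction, 0 at the pial circle). The closed-form equal-area law
    for this geometry is ``r_k = sqrt(r_out^2 - (k/K)(r_out^2 - r_in^2))``.
    """
    if not (0 < r_in < r_out < min(image_shape) / 2):
        raise ValueError("need 0 < r_in < r_out < min(image_shape)/2")
    center = ((image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0)
    r, _, _, _ = _polar(image_shape, center)
    wm = r < r_in
    gm = (r >= r_in) & (r < r_out)
    depth = (r_out - r) / (r_out - r_in)
    darkness = np.zeros(image_shape)
    darkness[wm] = wm_darkness
    darkness[gm] = np.clip(np.asarray(profile(depth[gm]), float),
                           _DARKNESS_LO, _DARKNESS_HI)
    darkness = _quantize(darkness)

    labels = np.zeros(image_shape, np.uint8)
    labels[gm] = LABEL_GM
    labels[wm] = LABEL_WM
    outer, inner = boundary_masks(labels)
    sec = StainSection(image=_export_uint8(darkness, wm | gm), stain=stain,
                       index=index)
    seg = SegmentedSection(labels=labels, outer_boundary=outer,
                           inner_boundary=inner, index=index, stain=stain)
    return sec, seg


def perturb_roi(mask: np.ndarray, jitter: float, dilation: int, seed: int,
                gm: np.ndarray | None = None,
                direction: tuple[float, float] | None = None) -> np.ndarray:
    """Jittered copy of an ROI mask, emulating a probabilistic atlas definition.

    Translates by a random integer offset of magnitude <= ``jitter`` px
    (along ``direction`` if given, otherwise a random direction), dilates
    (``dilation`` > 0) or erodes (< 0), and clips to GM if given.
    Deterministic in ``seed``.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    rng = np.random.default_rng(seed)
    if jitter > 0:
        if direction is None:
            ang = rng.uniform(0, 2 * np.pi)
            d = np.array([np.sin(ang), np.cos(ang)])
        else:
            d = np.asarray(direction, float)
            d = d / max(np.linalg.norm(d), 1e-12)
            d = d * rng.choice([-1.0, 1.0])
        rad = rng.uniform(0.6, 1.0) * jitter  # mostly-substantial displacement
        offset = (int(round(rad * d[0])), int(round(rad * d[1])))
    else:
        offset = (0, 0)
    out = ndimage.shift(mask.astype(np.uint8), offset, order=0,
                        mode="constant", cval=0).astype(bool)
    if dilation > 0:
        out = ndimage.binary_dilation(out, disk(dilation))
    elif dilation < 0:
        out = ndimage.binary_erosion(out, disk(-dilation))
    if gm is not None:
        out &= np.asarray(gm, bool)
    if not out.any():
        raise ValueError("perturbation emptied the ROI mask")
    return out
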