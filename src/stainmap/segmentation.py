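"""Background/GM/WM segmentation of stained sections.

Gray and white matter are separated by exact multilevel Otsu thresholding of
the brain-pixel intensity histogram. GM is identified as the thresholded
class with the greater 4-connected contact with the image background: the
cortical ribbon abuts the outside of the brain, the white matter does not.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (LABEL_BACKGROUND, LABEL_GM, LABEL_WM, SegmentedSection,
                   StainSection)

#: 4-connected structuring element
CROSS = ndimage.generate_binary_structure(2, 1)


class DegenerateHistogramError(ValueError):
    """Histogram has fewer populated intensity values than requested classes."""


def multilevel_threshold(histogram: np.ndarray, n_classes: int = 2) -> tuple[int, ...]:
    """Exact multilevel Otsu thresholds for a 256-bin intensity histogram.

    Maximizes the between-class variance over all ordered tuples of cut
    values; class ``k`` spans intensities ``(t_{k-1}, t_k]`` with cuts
    returned strictly increasing. Ties are broken toward the lowest tuple.

    Parameters
    ----------
    histogram : (256,) array of counts
    n_classes : number of classes (>= 2); returns ``n_classes - 1`` cuts

    Notes
    -----
    Between-class variance equals ``sum_k w_k mu_k^2 - mu_T^2``; maximizing
    ``sum_k w_k mu_k^2`` is equivalent and is what is scanned exhaustively
    using cumulative sums (255 cuts for 2 classes, all pairs for 3).
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("histogram must have 256 bins")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    total = hist.sum()
    if total <= 0:
        raise DegenerateHistogramError("empty histogram")
    if np.count_nonzero(hist) < n_classes:
        raise DegenerateHistogramError(
            f"need at least {n_classes} populated intensity values")

    p = hist / total
    levels = np.arange(256, dtype=float)
    w_cum = np.cumsum(p)                      # P(value <= t)
    m_cum = np.cumsum(p * levels)             # E[value * 1(value <= t)]

    def class_term(lo: np.ndarray, hi: np.ndarray):
        """w * mu^2 for classes spanning (lo, hi]; lo, hi are cut indices."""
        w = w_cum[hi] - np.where(lo < 0, 0.0, w_cum[np.maximum(lo, 0)])
        m = m_cum[hi] - np.where(lo < 0, 0.0, m_cum[np.maximum(lo, 0)])
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(w > 0, m * m / np.where(w > 0, w, 1.0), 0.0)
        return out

    if n_classes == 2:
        t = np.arange(255)
        crit = class_term(np.full(255, -1), t) + class_term(t, np.full(255, 255))
        best = int(np.argmax(crit))           # argmax returns first maximum
        return (best,)
    if n_classes == 3:
        best_val = -np.inf
        best_cut = (0, 1)
        t2 = np.arange(255)
        for t1 in range(254):
            upper = t2[t1 + 1:]
            crit = (class_term(np.full(upper.size, -1), np.full(upper.size, t1))
                    + class_term(np.full(upper.size, t1), upper)
                    + class_term(upper, np.full(upper.size, 255)))
            j = int(np.argmax(crit))
            if crit[j] > best_val:
                best_val = float(crit[j])
                best_cut = (t1, int(upper[j]))
        return best_cut
    # generic recursive scan for n_classes > 3 (rarely needed; exact but slow)
    from itertools import combinations
    best_val, best_cut = -np.inf, None
    for cuts in combinations(range(255), n_classes - 1):
        bounds = (-1,) + cuts + (255,)
        val = sum(float(class_term(np.array([a]), np.array([b]))[0])
                  for a, b in zip(bounds[:-1], bounds[1:]))
        if val > best_val:
            best_val, best_cut = val, cuts
    return best_cut


def boundary_masks(labels: np.ndarray, connectivity: int = 1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Outer (GM|background) and inner (GM|WM) boundary masks of a label image."""
    struct = ndimage.generate_binary_structure(2, connectivity)
    gm = labels == LABEL_GM
    bg = labels == LABEL_BACKGROUND
    wm = labels == LABEL_WM
    outer = gm & ndimage.binary_dilation(bg, struct)
    inner = gm & ndimage.binary_dilation(wm, struct)
    return outer, inner


def segment_section(section: StainSection, min_island_px: int = 50,
                    connectivity: int = 1) -> SegmentedSection:
    """Segment a section into background / GM (127) / WM (255).

    Brain pixels (non-zero) are split into two classes by 2-class Otsu on
    their histogram; the class with more pixels touching the background is
    labeled GM. GM islands smaller than ``min_island_px`` are reassigned to
    WM before boundary extraction.
    """
    img = np.asarray(section.image)
    brain = img > 0
    if not brain.any():
        raise ValueError("empty brain mask")
    hist = np.bincount(img[brain].ravel(), minlength=256).astype(float)
    (t,) = multilevel_threshold(hist, n_classes=2)
    class_low = brain & (img <= t)
    class_high = brain & (img > t)

    bg_dilated = ndimage.binary_dilation(~brain, CROSS)
    contact_low = int(np.count_nonzero(class_low & bg_dilated))
    contact_high = int(np.count_nonzero(class_high & bg_dilated))
    gm = class_low if contact_low >= contact_high else class_high
    wm = brain & ~gm

    # drop small GM islands (staining noise) into WM
    lab, n = ndimage.label(gm, structure=ndimage.generate_binary_structure(2, 2))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_island_px) + 1
        if small.size:
            drop = np.isin(lab, small)
            gm = gm & ~drop
            wm = wm | drop

    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[gm] = LABEL_GM
    labels[wm] = LABEL_WM
    outer, inner = boundary_masks(labels, connectivity=connectivity)
    return SegmentedSection(labels=labels, outer_boundary=outer,
                            inner_boundary=inner, index=section.index,
                            stain=section.stain)
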