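"""Equi-volume cortical depth bins and columnar (tangential) distance.

Depth estimation proceeds in three steps per GM component:

1. an equidistant depth field ``alpha = d_outer / (d_outer + d_inner)``
   from Euclidean distance transforms to the two GM boundaries;
2. a partition of GM into tangential *columns*: mid-depth pixels
   (``alpha`` in a window around 0.5) are ordered along their arc, every GM
   pixel adopts the arc position of its nearest mid-depth pixel, and the
   arc is cut into columns of fixed width;
3. an equi-volume reparameterization per column: the continuous depth of a
   pixel is its area-rank of ``alpha`` within its column, so each of the K
   depth bins encloses the same tissue area inside every column.

Because step 3 is a rank (cumulative-area) inversion, it is invariant to
any monotone depth field and reproduces the closed-form equal-area law on
an annulus: bin boundaries at radii ``r_k = sqrt(r_out^2 -
(k/K)(r_out^2 - r_in^2))``, strictly closer to the convex outer surface
than equidistant boundaries ("outer layers have thinner volume").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from skimage.graph import MCP_Geometric
from skimage.morphology import skeletonize

from .core import SegmentedSection

logger = logging.getLogger(__name__)

DEFAULT_K = 15
MID_WINDOW = (0.45, 0.55)


@dataclass
class DepthField:
    """Per-GM-pixel continuous equi-volume depth, depth bin, and column id."""

    depth: np.ndarray        # float in (0, 1]; NaN outside GM
    bin_index: np.ndarray    # int 1..K inside GM; 0 outside
    column_id: np.ndarray    # int >= 0 inside GM; -1 outside
    equidistant: np.ndarray  # the monotone pre-reparameterization field
    arc: np.ndarray          # continuous tangential arc coordinate (px); NaN outside
    n_bins: int
    mid_window: tuple[float, float] = MID_WINDOW
    column_width_px: float = 20.0

    @property
    def gm_mask(self) -> np.ndarray:
        return self.bin_index > 0


@dataclass
class ColumnField:
    """Tangential distance along the mid layer, inherited by all depths."""

    distance: np.ndarray     # px along the mid-layer arc; NaN outside ROI GM
    normalized: np.ndarray   # distance / max distance, in [0, 1]
    bin_index: np.ndarray    # columnar bin; -1 outside
    roi_mask: np.ndarray
    bin_width_px: float
    total_length_px: float


class DisconnectedMidLayerError(RuntimeError):
    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"middle layer is disconnected inside the ROI "
            f"({n_components} components)")


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3))
    k[1, 1] = 0
    return ndimage.convolve(mask.astype(int), k, mode="constant")


def _order_open_curve(coords: np.ndarray, mask_shape) -> np.ndarray:
    """Order skeleton pixels along an open curve via geodesic distance."""
    cost = np.full(mask_shape, np.inf)
    cost[tuple(coords.T)] = 1.0
    mcp = MCP_Geometric(cost, fully_connected=True)
    dist0, _ = mcp.find_costs([tuple(coords[0])])
    d0 = dist0[tuple(coords.T)]
    if not np.all(np.isfinite(d0)):
        raise DisconnectedMidLayerError(
            int(ndimage.label(cost < np.inf,
                              ndimage.generate_binary_structure(2, 2))[1]))
    end_a = coords[int(np.argmax(d0))]
    dist_a, _ = mcp.find_costs([tuple(end_a)])
    da = dist_a[tuple(coords.T)]
    end_b = coords[int(np.argmax(da))]
    # orient deterministically: start at the end with the smaller (col, row)
    if tuple(end_b[::-1]) < tuple(end_a[::-1]):
        dist_b, _ = mcp.find_costs([tuple(end_b)])
        da = dist_b[tuple(coords.T)]
    return np.argsort(da, kind="stable")


def _midline_polyline(band: np.ndarray, smooth_window: int = 7
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed centerline polyline of a thin band mask, with arc length.

    The band is skeletonized, the skeleton ordered along its run (open
    curves by geodesic ordering; closed loops by angle around the
    centroid, which assumes a star-shaped loop), coordinates smoothed by a
    moving average, and arc length accumulated as the Euclidean polyline
    length. Returns (points (n, 2), arclength (n,)); any pixel set can be
    given an arc coordinate by querying its nearest polyline point.
    """
    band = np.asarray(band, bool)
    skel = skeletonize(band)
    if np.count_nonzero(skel) < 2:
        skel = band
    lab, n = ndimage.label(skel, ndimage.generate_binary_structure(2, 2))
    if n > 1:  # stray fragments: keep the main run of the mid line
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, n + 1))
        skel = lab == (1 + int(np.argmax(sizes)))
    coords = np.column_stack(np.nonzero(skel))
    nb = _neighbor_count(skel)
    endpoints = skel & (nb == 1)
    if endpoints.any():
        order = _order_open_curve(coords, band.shape)
    else:  # closed loop
        ctr = coords.mean(axis=0)
        ang = np.arctan2(coords[:, 0] - ctr[0], coords[:, 1] - ctr[1])
        order = np.argsort(ang, kind="stable")
    pts = coords[order].astype(float)
    if len(pts) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        sm = np.empty_like(pts)
        for d in range(2):
            col = np.pad(pts[:, d], pad, mode="edge")
            sm[:, d] = np.convolve(col, kernel, mode="valid")
    else:
        sm = pts
    seglen = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    closed = not endpoints.any()
    if closed:
        total = float(arc[-1] + np.linalg.norm(sm[-1] - sm[0]))
    else:
        total = float(arc[-1])
    return sm, arc, closed, total


def _arclength_of_band(band: np.ndarray, smooth_window: int = 7
                       ) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Arc-length coordinate for every pixel of a thin band mask.

    Returns (band pixel coords, arc values, closed flag, total length).
    """
    band = np.asarray(band, bool)
    pts, arc, closed, total = _midline_polyline(band, smooth_window)
    band_coords = np.column_stack(np.nonzero(band))
    _, nearest = cKDTree(pts).query(band_coords)
    return band_coords, arc[nearest], closed, total


def _trace_to_mid(alpha: np.ndarray, comp_mask: np.ndarray,
                  coords: np.ndarray, step: float = 0.5,
                  tol: float = 0.02, max_steps: int = 400) -> np.ndarray:
    """Trace depth-gradient streamlines from ``coords`` to the mid level.

    Follows the (bilinearly interpolated) gradient of the smoothed depth
    field toward alpha = 0.5 and returns the landing points. Tracing in
    the continuous field avoids the grid anisotropy of pixel-neighbor
    schemes, so columns follow the true orthogonal trajectories.
    """
    # extend alpha outside GM by nearest-GM value so border gradients behave
    nearest = ndimage.distance_transform_edt(~comp_mask, return_indices=True)[1]
    a = alpha[tuple(nearest)]
    a = ndimage.gaussian_filter(a, 1.0)
    gy, gx = np.gradient(a)

    pos = coords.astype(float).copy()
    active = np.ones(len(pos), bool)
    h, w = a.shape
    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        av = ndimage.map_coordinates(a, p.T, order=1)
        done = np.abs(av - 0.5) < tol
        if done.any():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            p = pos[active]
            if p.size == 0:
                break
            av = ndimage.map_coordinates(a, p.T, order=1)
        vy = ndimage.map_coordinates(gy, p.T, order=1)
        vx = ndimage.map_coordinates(gx, p.T, order=1)
        norm = np.hypot(vy, vx)
        norm[norm < 1e-9] = 1e-9
        sgn = np.sign(av - 0.5)
        p = p - step * sgn[:, None] * np.column_stack([vy, vx]) / norm[:, None]
        p[:, 0] = np.clip(p[:, 0], 0, h - 1)
        p[:, 1] = np.clip(p[:, 1], 0, w - 1)
        pos[active] = p
    return pos


def _propagate_arc(comp_mask: np.ndarray, alpha: np.ndarray,
                   band: np.ndarray, band_arc: np.ndarray,
                   closed: bool = False, period: float = 0.0) -> np.ndarray:
    """Arc coordinate for every component pixel via streamline columns.

    Every GM pixel is traced along the depth gradient to the mid layer and
    inherits the arc-length coordinate of the nearest mid-band pixel at
    its landing point.
    """
    band_coords = np.column_stack(np.nonzero(band))
    tree = cKDTree(band_coords)
    coords = np.column_stack(np.nonzero(comp_mask))
    landing = _trace_to_mid(alpha, comp_mask, coords)
    _, j = tree.query(landing)
    arc = np.full(comp_mask.shape, np.nan)
    arc[tuple(coords.T)] = band_arc[j]
    return arc


def _equidistant_field(seg: SegmentedSection) -> np.ndarray:
    if not seg.outer_boundary.any() or not seg.inner_boundary.any():
        raise ValueError("both GM boundaries must be nonempty")
    d_out = ndimage.distance_transform_edt(~seg.outer_boundary)
    d_in = ndimage.distance_transform_edt(~seg.inner_boundary)
    with np.errstate(invalid="ignore"):
        alpha = d_out / (d_out + d_in)
    alpha[~seg.gm_mask] = np.nan
    return alpha


def equivolume_depth(seg: SegmentedSection, n_bins: int = DEFAULT_K,
                     column_width_px: float = 20.0,
                     mid_window: tuple[float, float] = MID_WINDOW) -> DepthField:
    """Equi-volume depth bins (1 = outermost) on a segmented section."""
    gm = seg.gm_mask
    if not gm.any():
        raise ValueError("empty GM")
    alpha = _equidistant_field(seg)

    depth = np.full(seg.labels.shape, np.nan)
    bins = np.zeros(seg.labels.shape, np.int16)
    columns = np.full(seg.labels.shape, -1, np.int32)
    arc_all = np.full(seg.labels.shape, np.nan)

    structure = ndimage.generate_binary_structure(2, 2)
    comp_lab, n_comp = ndimage.label(gm, structure)
    col_offset = 0
    for comp in range(1, n_comp + 1):
        comp_mask = comp_lab == comp
        a = alpha.copy()
        a[~comp_mask] = np.nan
        band = comp_mask & (a >= mid_window[0]) & (a <= mid_window[1])
        if not band.any():  # very thin GM: use the middle half
            band = comp_mask & (a >= 0.25) & (a <= 0.75)
        if not band.any():
            band = comp_mask
        band_coords, band_arc, closed, total = _arclength_of_band(band)
        band_arc_img = np.zeros(band.shape)
        band_arc_img[tuple(band_coords.T)] = band_arc
        arc_img = _propagate_arc(comp_mask, np.nan_to_num(a, nan=0.5),
                                 band, band_arc_img[band],
                                 closed=closed, period=total)
        px = np.column_stack(np.nonzero(comp_mask))
        arc = arc_img[tuple(px.T)]
        col = np.floor(arc / column_width_px).astype(np.int32)

        # merge columns too small for K bins into their nearest valid column
        ids, counts = np.unique(col, return_counts=True)
        valid = ids[counts >= n_bins]
        if valid.size == 0:
            valid = ids[[int(np.argmax(counts))]]
        small = ids[counts < n_bins]
        if small.size:
            logger.warning("merging %d under-filled columns (< %d px)",
                           small.size, n_bins)
            remap = {s: valid[int(np.argmin(np.abs(valid - s)))] for s in small}
            col = np.array([remap.get(ci, ci) for ci in col], dtype=np.int32)

        a_px = np.nan_to_num(a[tuple(px.T)], nan=0.5)
        d_px = np.empty(len(px))
        for cid in np.unique(col):
            in_col = col == cid
            ranks = rankdata(a_px[in_col], method="average")
            d_px[in_col] = (ranks - 0.5) / in_col.sum()
        b_px = np.minimum(np.ceil(d_px * n_bins), n_bins).astype(np.int16)
        b_px[b_px < 1] = 1

        depth[tuple(px.T)] = d_px
        bins[tuple(px.T)] = b_px
        columns[tuple(px.T)] = col + col_offset
        arc_all[tuple(px.T)] = arc
        col_offset += int(col.max()) + 1

    return DepthField(depth=depth, bin_index=bins, column_id=columns,
                      equidistant=alpha, arc=arc_all, n_bins=n_bins,
                      mid_window=mid_window, column_width_px=column_width_px)


def columnar_distance(seg: SegmentedSection, roi: np.ndarray,
                      depth_field: DepthField, bin_width_px: float = 5.0,
                      mid_window: tuple[float, float] = (0.40, 0.60)
                      ) -> ColumnField:
    """Distance along the mid layer inside an ROI, inherited across depths.

    The geodesic arc length is measured along the chain of mid-depth pixels
    (continuous depth in ``mid_window``) from one end of the ROI; every
    other GM pixel inside the ROI inherits the distance of its nearest
    (Euclidean) mid-layer pixel, and distances are cut into columnar bins
    of ``bin_width_px``.
    """
    roi = np.asarray(roi, bool) & depth_field.gm_mask
    if not roi.any():
        raise ValueError("ROI does not intersect GM")
    # the smooth equidistant field defines the mid layer: the rank-based
    # equi-volume depth is discontinuous across column seams, which would
    # spuriously fragment the mid band
    mid = np.nan_to_num(depth_field.equidistant, nan=-1.0)
    band = roi & (mid >= mid_window[0]) & (mid <= mid_window[1])
    if not band.any():
        raise ValueError("ROI does not intersect the middle depth layer")
    n_comp = int(ndimage.label(band, ndimage.generate_binary_structure(2, 2))[1])
    if n_comp > 1:
        raise DisconnectedMidLayerError(n_comp)
    band_coords, band_arc, _, _ = _arclength_of_band(band)

    distance = np.full(roi.shape, np.nan)
    px = np.column_stack(np.nonzero(roi))
    _, nearest = cKDTree(band_coords).query(px)
    distance[tuple(px.T)] = band_arc[nearest]

    total = float(np.nanmax(distance))
    normalized = distance / total if total > 0 else np.where(roi, 0.0, np.nan)
    bins = np.full(roi.shape, -1, np.int32)
    bins[roi] = np.floor(distance[roi] / bin_width_px).astype(np.int32)
    return ColumnField(distance=distance, normalized=normalized,
                       bin_index=bins, roi_mask=roi, bin_width_px=bin_width_px,
                       total_length_px=total)
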