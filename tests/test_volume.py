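"""Volume alignment, slice-correlation validation, and ROI projection."""

import numpy as np
import pytest
import SimpleITK as sitk
from scipy import ndimage

from stainmap.core import STAIN_CO
from stainmap.laminar import equivolume_depth
from stainmap.phantom import default_config, generate_phantom
from stainmap.registration import stack_to_volume
from stainmap.volume import (VolumeTransform, align_volumes, dice,
                             extend_roi_across_depth, project_roi,
                             validate_alignment)


@pytest.fixture(scope="module")
def phantom20():
    return generate_phantom(default_config(n_sections=20, seed=4))


# ---------------------------------------------------------------- dice

def test_dice_identity_and_disjoint():
    a = np.zeros((10, 10), bool)
    a[2:6, 2:6] = True
    b = np.zeros((10, 10), bool)
    b[7:9, 7:9] = True
    assert dice(a, a) == 1.0
    assert dice(a, b) == 0.0


def test_dice_hand_count():
    a = np.zeros(200, bool)
    b = np.zeros(200, bool)
    a[:100] = True
    b[50:150] = True
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_both_empty_errors():
    with pytest.raises(ValueError):
        dice(np.zeros(5, bool), np.zeros(5, bool))


# ----------------------------------------------------------- validation

def test_identical_volumes_correlate_perfectly():
    rng = np.random.default_rng(0)
    vol = rng.random((6, 20, 20)) + 0.1
    rep = validate_alignment(vol, vol)
    assert np.allclose(rep.correlations, 1.0)


def test_degenerate_slice_is_excluded():
    rng = np.random.default_rng(1)
    vol = rng.random((5, 16, 16)) + 0.1
    other = vol.copy()
    other[2] = 0.0
    rep = validate_alignment(vol, other)
    assert 2 in rep.excluded_slices


def test_axis_out_of_range_errors():
    v = np.zeros((4, 8, 8))
    with pytest.raises(ValueError):
        validate_alignment(v, v, axis=3)


def test_phantom_pair_separates_from_null(phantom20):
    """Corresponding slices beat the non-corresponding null (both stains)."""
    ds = phantom20
    ref = ds.reference_volume
    n = ds.n_sections
    for stain, as_intensity in ((STAIN_CO, True), ("myelin", False)):
        idx = [i for i in range(n)
               if (i % 2 == 0) == (stain == STAIN_CO)]
        stack = []
        for i in idx:
            brain = ds.clean_segmentations[i].labels > 0
            d = ds.clean_sections[i]
            stack.append(np.where(brain, (1.0 - d) if as_intensity else d,
                                  0.0))
        rep = validate_alignment(np.stack(stack), ref[idx], seed=2)
        # oracle: recompute one corresponding and one null r by direct loop
        a, b = stack[3], ref[idx][3]
        m = (a != 0) & (b != 0)
        r_direct = np.corrcoef(a[m], b[m])[0, 1]
        assert rep.correlations[3] == pytest.approx(r_direct, abs=1e-12)
        assert np.nanmedian(rep.correlations) > rep.null_q95


# ------------------------------------------------------------ alignment

def test_self_alignment_is_near_identity(phantom20):
    ref = phantom20.reference_volume
    tf = align_volumes(ref, ref, sampling_fraction=0.5,
                       iterations=(50, 25, 10))
    aligned = tf.resample_into_reference(ref, ref.shape)
    rep = validate_alignment(aligned, ref)
    assert np.nanmean(rep.correlations) >= 0.999


def test_planted_affine_recovered_within_one_voxel(phantom20):
    ref = phantom20.reference_volume
    th = np.deg2rad(3.0)
    c, s = np.cos(th), np.sin(th)
    mat = np.array([[1, 0, 0], [0, c, -s], [0, s, c]]) * 1.05
    center = np.array([10.0, 96.0, 96.0])
    off = center - mat @ center + np.array([0.0, 4.0, 0.0])
    moved_ref = ndimage.affine_transform(ref, mat, offset=off, order=1)
    tf = align_volumes(ref, moved_ref, sampling_fraction=0.5,
                       iterations=(50, 25, 10))
    assert tf.converged
    pts = np.array([[10, 96, 96], [5, 60, 120], [15, 120, 60],
                    [18, 140, 140], [2, 50, 50]], float)
    mapped = tf.map_reference_points(pts)
    truth = (mat @ pts.T).T + off
    assert np.linalg.norm(mapped - truth, axis=1).mean() < 1.0


def test_nonlinear_refinement_runs_and_is_smooth(phantom20):
    """Optional demons stage: produces a displacement field, keeps r high."""
    small = phantom20.reference_volume[:, ::3, ::3].copy()
    tf = align_volumes(small, small, nonlinear=True, iterations=(20, 10),
                       sampling_fraction=0.5, demons_iterations=5)
    assert tf.displacement is not None
    # self-alignment: the refinement must not invent large displacements
    assert np.abs(tf.displacement).max() < 1.5
    aligned = tf.resample_into_reference(small, small.shape)
    rep = validate_alignment(aligned, small)
    assert np.nanmean(rep.correlations) > 0.99


def test_noise_reference_is_flagged_or_uncorrelated(phantom20):
    rng = np.random.default_rng(3)
    noise = rng.random(phantom20.reference_volume.shape)
    tf = align_volumes(phantom20.reference_volume, noise,
                       sampling_fraction=0.5, iterations=(20, 10))
    aligned = tf.resample_into_reference(phantom20.reference_volume,
                                         noise.shape)
    rep = validate_alignment(aligned, noise)
    assert (not tf.converged) or abs(np.nanmean(rep.correlations)) < 0.2


# -------------------------------------------------------- ROI projection

def test_extension_covers_full_depth_and_is_idempotent(phantom20):
    seg = phantom20.clean_segmentations[10]
    df = equivolume_depth(seg)
    # ROI restricted to the outer bins of a tangential interval
    roi = seg.gm_mask & (df.bin_index <= 7) \
        & (df.arc >= 100) & (df.arc <= 150)
    ext = extend_roi_across_depth(roi, df)
    covered_bins = np.unique(df.bin_index[ext])
    assert set(range(1, 16)) <= set(covered_bins.tolist())
    assert np.array_equal(extend_roi_across_depth(ext, df), ext)


def test_extension_of_full_depth_interval_is_noop(phantom20):
    seg = phantom20.clean_segmentations[10]
    df = equivolume_depth(seg)
    roi = seg.gm_mask & (df.arc >= 100) & (df.arc <= 150)
    assert np.array_equal(extend_roi_across_depth(roi, df), roi)


def test_project_roi_identity_transform(phantom20):
    ds = phantom20
    segs = ds.clean_segmentations
    dfs = [equivolume_depth(s) for s in segs]
    roi_vol = np.stack([m.astype(float) for m in ds.roi_masks["ML"]])
    tf = VolumeTransform(forward=sitk.Transform(3, sitk.sitkIdentity))
    out = project_roi(roi_vol, tf, segs, dfs,
                      section_slices={i: i for i in range(ds.n_sections)},
                      histo_shape=roi_vol.shape)
    hit = [i for i, m in out.items() if m.any()]
    assert len(hit) > 5
    i = hit[len(hit) // 2]
    # projected mask contains the truth ROI and spans all depth bins
    truth = ds.roi_masks["ML"][i] & segs[i].gm_mask
    assert np.count_nonzero(truth & ~out[i]) / truth.sum() < 0.05
    assert set(range(1, 16)) <= set(np.unique(dfs[i].bin_index[out[i]]))


def test_project_roi_in_wm_errors(phantom20):
    ds = phantom20
    segs = ds.clean_segmentations
    dfs = [equivolume_depth(s) for s in segs[:4]]
    rows, cols = np.indices(segs[0].labels.shape)
    core = np.hypot(rows - 96.0, cols - 96.0) < 20  # deep WM, off the cortex
    wm_vol = np.stack([(s.wm_mask & core).astype(float) for s in segs[:4]])
    tf = VolumeTransform(forward=sitk.Transform(3, sitk.sitkIdentity))
    with pytest.raises(ValueError):
        project_roi(wm_vol, tf, segs[:4], dfs,
                    section_slices={i: i for i in range(4)},
                    histo_shape=wm_vol.shape)
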