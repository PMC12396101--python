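"""Depth profiles, between-ROI statistics, and tangential maps."""

import numpy as np
import pytest

from stainmap.laminar import columnar_distance, equivolume_depth
from stainmap.phantom import default_config, generate_phantom
from stainmap.profiles import (DepthProfile, build_tangential_map,
                               compare_patches_ttest, depth_profile,
                               face_vs_nonface, fdr_correct,
                               laminar_similarity, normalize_stain,
                               outer_inner_means, section_intensities)


# -------------------------------------------------------- normalization

def test_normalization_endpoints_and_midpoint():
    img = np.array([[255, 0, 127]], dtype=np.uint8)
    dark = normalize_stain(img)
    assert dark[0, 0] == 0.0
    assert dark[0, 1] == 1.0
    assert dark[0, 2] == pytest.approx(1 - 127 / 255)


def test_normalization_reverses_order():
    rng = np.random.default_rng(0)
    raw = rng.integers(0, 256, 50)
    dark = normalize_stain(raw)
    # affine and order-reversing: darkness decreases as raw increases
    assert np.all(np.diff(dark[np.argsort(raw, kind="stable")]) <= 0)


# ------------------------------------------------------------- profiles

def test_uniform_darkness_gives_flat_profile(slab):
    df = equivolume_depth(slab)
    dark = np.full(slab.labels.shape, 0.5)
    prof = depth_profile([dark], [df], [slab.gm_mask])
    assert np.allclose(prof.matrix, 0.5)


def test_linear_profile_recovers_bin_centers(slab):
    """darkness = depth: bin means land at (2k-1)/30."""
    df = equivolume_depth(slab)
    rows = np.indices(slab.labels.shape)[0]
    dark = np.clip((rows - 9.5) / 30.0, 0, 1)  # linear across GM rows 10..39
    cols = np.indices(slab.labels.shape)[1]
    roi = slab.gm_mask & (cols >= 45) & (cols < 115)
    prof = depth_profile([dark], [df], [roi])
    centers = (2 * np.arange(1, 16) - 1) / 30.0
    assert np.abs(prof.matrix[0] - centers).max() < 0.02


def test_band_profile_peaks_in_middle_bins(slab):
    df = equivolume_depth(slab)
    dark = np.where((df.depth >= 0.45) & (df.depth <= 0.55)
                    & slab.gm_mask, 0.9, 0.2)
    prof = depth_profile([dark], [df], [slab.gm_mask])
    assert int(np.argmax(prof.matrix[0])) + 1 in (7, 8)


def test_profile_union_is_weighted_average(slab):
    df = equivolume_depth(slab)
    rng = np.random.default_rng(1)
    dark = rng.random(slab.labels.shape)
    cols = np.indices(slab.labels.shape)[1]
    roi_a = slab.gm_mask & (cols >= 30) & (cols < 60)
    roi_b = slab.gm_mask & (cols >= 90) & (cols < 140)
    pa = depth_profile([dark], [df], [roi_a]).matrix[0]
    pb = depth_profile([dark], [df], [roi_b]).matrix[0]
    pu = depth_profile([dark], [df], [roi_a | roi_b]).matrix[0]
    for k in range(15):
        na = np.count_nonzero(roi_a & (df.bin_index == k + 1))
        nb = np.count_nonzero(roi_b & (df.bin_index == k + 1))
        assert pu[k] == pytest.approx((na * pa[k] + nb * pb[k]) / (na + nb))


def test_empty_roi_errors(slab):
    df = equivolume_depth(slab)
    with pytest.raises(ValueError):
        depth_profile([np.zeros(slab.labels.shape)], [df],
                      [np.zeros(slab.labels.shape, bool)])


# ----------------------------------------------------------- similarity

def test_laminar_similarity_examples():
    p = np.array([0.2, 0.5, 0.4, 0.7, 0.3])
    assert laminar_similarity(p, p) == pytest.approx(1.0)
    assert laminar_similarity(p, 2 * p.mean() - p) == pytest.approx(-1.0)
    assert laminar_similarity([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        laminar_similarity([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------- outer/inner

def _profile_from_rows(rows):
    m = np.asarray(rows, float)
    return DepthProfile(roi="x", stain="co", matrix=np.atleast_2d(m),
                        section_ids=list(range(np.atleast_2d(m).shape[0])))


def test_outer_inner_split_convention():
    prof = _profile_from_rows(np.arange(1, 16))
    outer, inner = outer_inner_means(prof)
    assert outer[0] == pytest.approx(4.0)     # mean of bins 1..7
    assert inner[0] == pytest.approx(11.5)    # mean of bins 8..15


def test_outer_inner_constant_profile():
    prof = _profile_from_rows(np.full(15, 0.42))
    outer, inner = outer_inner_means(prof)
    assert outer[0] == inner[0] == pytest.approx(0.42)


def test_outer_inner_requires_fifteen_bins():
    prof = _profile_from_rows(np.arange(10))
    with pytest.raises(ValueError):
        outer_inner_means(prof)
    outer, _ = outer_inner_means(prof, split=5)
    assert outer[0] == pytest.approx(2.0)


# --------------------------------------------------------------- t-test

def test_ttest_identical_groups():
    t, df, p = compare_patches_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_ttest_hand_example():
    """Pooled-variance t for [1,2,3] vs [3,4,5]: t = -2.449, df = 4."""
    t, df, p = compare_patches_ttest([1, 2, 3], [3, 4, 5])
    assert df == 4
    assert t == pytest.approx(-2.449, abs=1e-3)
    assert p == pytest.approx(0.0705, abs=1e-3)


def test_ttest_needs_two_per_group():
    with pytest.raises(ValueError):
        compare_patches_ttest([1.0], [2.0, 3.0])


# ------------------------------------------------------------------ BH

def _bh_oracle(pvals, q):
    """Step-up rule evaluated literally."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    rejected = np.zeros(m, bool)
    rejected[order[:k_max]] = True
    return rejected


def test_bh_rejects_all_in_spec_example():
    rej, _ = fdr_correct([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert rej.all()


@pytest.mark.parametrize("seed", range(10))
def test_bh_matches_step_up_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 9))
    p = rng.random(n)
    rej, _ = fdr_correct(p, q=0.05)
    assert np.array_equal(rej, _bh_oracle(p, 0.05))


# ------------------------------------------------------ tangential maps

def _flat_gradient_phantom(grad=0.0, n=8):
    flat = {s: {k: (lambda v: np.full_like(np.asarray(v, float), 0.45))
                for k in ("base", "ML", "AL", "AFAD")}
            for s in ("co", "myelin")}
    return generate_phantom(default_config(
        n_sections=n, seed=3, laminar_profiles=flat,
        tangential_gradient=grad, misalignment_amplitude=(0, 0),
        drift_quad=(0, 0, 0), drift_hf_amplitude=0, noise_sd=0,
        texture_amplitude=0, span_shrink_deg_per_section=0.0,
        span_wiggle_deg=0.0, radius_wiggle_px=0.0, shrink_per_section=0.0))


def _map_inputs(ds, stains=("co",)):
    idx = [i for i in range(ds.n_sections)
           if ds.sections[i].stain in stains]
    cfs, dark = [], []
    for i in idx:
        seg = ds.clean_segmentations[i]
        df = equivolume_depth(seg)
        cfs.append(columnar_distance(seg, seg.gm_mask, df))
        dark.append(normalize_stain(ds.sections[i].image))
    masks = {n_: [m[i] for i in idx] for n_, m in ds.roi_masks.items()}
    return dark, cfs, masks, idx


def test_uniform_phantom_gives_constant_map():
    ds = _flat_gradient_phantom(grad=0.0)
    dark, cfs, masks, idx = _map_inputs(ds)
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx)
    assert np.ptp(tmap.grid) < 0.02


def test_sections_of_different_length_share_one_grid():
    ds = generate_phantom(default_config(n_sections=8, seed=2,
                                         misalignment_amplitude=(0, 0)))
    dark, cfs, masks, idx = _map_inputs(ds)
    assert len({cf.total_length_px for cf in cfs}) > 1
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx,
                                n_positions=80)
    assert tmap.grid.shape == (len(idx), 80)
    assert tmap.positions[0] == 0.0 and tmap.positions[-1] == 1.0


def test_planted_gradient_appears_as_ramp():
    ds = _flat_gradient_phantom(grad=0.2)
    dark, cfs, masks, idx = _map_inputs(ds)
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx)
    row = tmap.grid[0]
    sel = (tmap.positions > 0.1) & (tmap.positions < 0.9)
    # linear ramp up to the (conventional) orientation of the arc origin
    r = np.corrcoef(tmap.positions[sel], row[sel])[0, 1]
    assert abs(r) > 0.99


def test_uniform_phantom_face_diffs_are_zero():
    ds = _flat_gradient_phantom(grad=0.0, n=10)
    dark, cfs, masks, idx = _map_inputs(ds)
    # stagger ROI presence so every position has non-face rows
    for name, ms in masks.items():
        ms[0] = np.zeros_like(ms[0])
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx)
    res = face_vs_nonface(tmap)
    for v in res.mean_difference.values():
        assert abs(v) < 0.005


def test_gradient_cancels_in_positional_subtraction():
    """A purely tangential gradient is removed by the subtraction."""
    ds = _flat_gradient_phantom(grad=0.15, n=10)
    dark, cfs, masks, idx = _map_inputs(ds)
    for name, ms in masks.items():
        ms[0] = np.zeros_like(ms[0])
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx)
    res = face_vs_nonface(tmap)
    for v in res.mean_difference.values():
        assert abs(v) < 0.005


def test_planted_offset_is_recovered_in_face_diff():
    flat = {s: {"base": (lambda v: np.full_like(np.asarray(v, float), 0.45)),
                "ML": (lambda v: np.full_like(np.asarray(v, float), 0.50)),
                "AL": (lambda v: np.full_like(np.asarray(v, float), 0.45)),
                "AFAD": (lambda v: np.full_like(np.asarray(v, float), 0.45))}
            for s in ("co", "myelin")}
    ds = generate_phantom(default_config(
        n_sections=10, seed=3, laminar_profiles=flat,
        misalignment_amplitude=(0, 0), drift_quad=(0, 0, 0),
        drift_hf_amplitude=0, noise_sd=0, texture_amplitude=0,
        span_shrink_deg_per_section=0.0, span_wiggle_deg=0.0,
        radius_wiggle_px=0.0, shrink_per_section=0.0))
    dark, cfs, masks, idx = _map_inputs(ds)
    for name, ms in masks.items():
        ms[0] = np.zeros_like(ms[0])
    tmap = build_tangential_map(dark, cfs, roi_masks=masks, section_ids=idx)
    res = face_vs_nonface(tmap)
    assert res.mean_difference["ML"] == pytest.approx(0.05, abs=0.01)
    assert abs(res.mean_difference["AL"]) < 0.01
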