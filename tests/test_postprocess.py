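"""False-positive filters: closed-form cases plus brute-force oracle sweeps."""

import numpy as np
import pytest
from scipy import ndimage

from pclseg.errors import DegenerateInputError, ShapeError
from pclseg.postprocess import (PostprocessConfig, abdomen_mask,
                                filter_noncontact_cysts,
                                filter_outside_abdomen,
                                filter_small_components, postprocess_pipeline)

from oracles import flood_components, surviving_cysts, touches

CFG = PostprocessConfig()


def _blob(shape, center, r):
    g = np.ogrid[tuple(slice(0, n) for n in shape)]
    return sum((a - c) ** 2 for a, c in zip(g, center)) <= r * r


# -- abdomen mask -----------------------------------------------------------

def test_air_excluded_from_abdomen_mask(phantom_pair):
    ct, _ = phantom_pair
    mask = abdomen_mask(ct, CFG)
    assert not mask[ct.voxels < -900].any()
    assert mask.any()


def test_zero_erosion_is_filled_largest_component():
    hu = np.full((30, 30, 10), -1000.0, np.float32)
    hu[_blob(hu.shape, (14, 14, 5), 8)] = 40.0
    hu[16, 16, 5] = -800.0                       # internal air pocket -> filled
    hu[_blob(hu.shape, (3, 26, 5), 2)] = 40.0    # smaller second blob
    cfg = PostprocessConfig(erosion_radius=0)
    mask = abdomen_mask(hu, cfg)
    assert mask[16, 16, 5]                       # hole filled
    assert not mask[3, 26, 5]                    # small blob dropped


def test_largest_component_matches_bruteforce_labeling():
    rng = np.random.default_rng(0)
    hu = np.full((20, 20, 6), -1000.0, np.float32)
    hu[_blob(hu.shape, (7, 7, 3), 5)] = 30.0
    hu[_blob(hu.shape, (16, 16, 3), 2)] = 30.0
    cfg = PostprocessConfig(erosion_radius=0)
    mask = abdomen_mask(hu, cfg)
    comps = flood_components(hu >= cfg.abdomen_hu_threshold, 26)
    biggest = max(comps, key=len)
    assert {tuple(v) for v in np.argwhere(mask)} >= biggest


def test_empty_mask_is_degenerate():
    with pytest.raises(DegenerateInputError):
        abdomen_mask(np.full((8, 8, 8), -1000.0, np.float32), CFG)


def test_erosion_shrinks_mask(phantom_pair):
    ct, _ = phantom_pair
    m0 = abdomen_mask(ct, PostprocessConfig(erosion_radius=0))
    m3 = abdomen_mask(ct, PostprocessConfig(erosion_radius=3))
    assert m3.sum() < m0.sum()
    assert not (m3 & ~m0).any()


# -- abdomen filter ---------------------------------------------------------

def test_prediction_inside_mask_unchanged():
    pred = np.zeros((10, 10, 6), np.int16)
    pred[4:6, 4:6, 2:4] = 2
    pred[2:4, 4:6, 2:4] = 1
    mask = np.ones_like(pred, bool)
    out, recs = filter_outside_abdomen(pred, mask, CFG)
    assert np.array_equal(out, pred)
    assert all(r.removed_by == "none" for r in recs)


def test_voxel_outside_mask_removed():
    pred = np.zeros((8, 8, 4), np.int16)
    pred[0, 0, 0] = 2
    mask = np.zeros_like(pred, bool)
    mask[2:6, 2:6, 1:3] = True
    out, recs = filter_outside_abdomen(pred, mask, CFG)
    assert out.sum() == 0
    assert len(recs) == 1 and recs[0].removed_by == "abdomen"
    assert not recs[0].inside_abdomen


def test_straddling_component_keeps_inside_voxels_only():
    pred = np.zeros((10, 8, 4), np.int16)
    pred[3:7, 4, 2] = 2                     # 4-voxel line crossing the border
    mask = np.zeros_like(pred, bool)
    mask[:5] = True                         # x < 5 inside
    out, recs = filter_outside_abdomen(pred, mask, CFG)
    assert (out == 2).sum() == 2            # hand count: x = 3, 4 survive
    assert recs[0].removed_by == "none"


def test_filter_shape_mismatch():
    with pytest.raises(ShapeError):
        filter_outside_abdomen(np.zeros((4, 4, 4), np.int16),
                               np.ones((4, 4, 5), bool), CFG)


# -- contact filter ---------------------------------------------------------

def _pred_with(pancreas_at, cyst_at):
    pred = np.zeros((12, 12, 8), np.int16)
    pred[pancreas_at] = 1
    pred[cyst_at] = 2
    return pred


def test_face_contact_retained():
    pred = _pred_with((slice(2, 5), slice(2, 5), slice(2, 5)),
                      (5, 3, 3))            # face-adjacent to pancreas at x=4
    out, recs = filter_noncontact_cysts(pred, CFG)
    assert (out == 2).sum() == 1
    assert recs[0].removed_by == "none" and recs[0].touches_pancreas


def test_isolated_cyst_removed():
    pred = _pred_with((slice(2, 4), slice(2, 4), slice(2, 4)),
                      (10, 10, 6))
    out, recs = filter_noncontact_cysts(pred, CFG)
    assert (out == 2).sum() == 0
    assert recs[0].removed_by == "contact"


def test_corner_contact_depends_on_connectivity():
    """Diagonal corner contact counts under 26-connectivity, not under 6."""
    pred = _pred_with((slice(2, 4), slice(2, 4), slice(2, 4)),
                      (4, 4, 4))            # corner-touches pancreas at (3,3,3)
    out26, _ = filter_noncontact_cysts(pred, PostprocessConfig(contact_connectivity=26))
    out6, _ = filter_noncontact_cysts(pred, PostprocessConfig(contact_connectivity=6))
    assert (out26 == 2).sum() == 1
    assert (out6 == 2).sum() == 0


def test_no_pancreas_removes_all_cysts():
    pred = np.zeros((8, 8, 8), np.int16)
    pred[_blob(pred.shape, (4, 4, 4), 2)] = 2
    out, recs = filter_noncontact_cysts(pred, CFG)
    assert (out == 2).sum() == 0
    assert recs and all(r.removed_by == "contact" for r in recs)


# -- size filter ------------------------------------------------------------

@pytest.mark.parametrize("size", range(1, 21))
def test_size_sweep_survival_iff_at_least_minimum(size):
    """Single components of 1..20 voxels survive exactly when >= 10."""
    pred = np.zeros((30, 10, 10), np.int16)
    pred[:size, 2, 2] = 2                   # one straight line of `size` voxels
    pred[:, 5, 5] = 1                       # pancreas line keeps contact filter moot
    out, recs = filter_small_components(pred, CFG)
    survived = (out == 2).sum() == size
    assert survived == (size >= CFG.min_cyst_voxels)
    assert recs[0].removed_by == ("none" if size >= 10 else "size")


def test_empty_prediction_empty_report():
    out, recs = filter_small_components(np.zeros((8, 8, 8), np.int16), CFG)
    assert out.sum() == 0 and recs == []


# -- pipeline ---------------------------------------------------------------

def test_clean_phantom_prediction_unchanged(phantom_pair):
    ct, lab = phantom_pair
    out, recs = postprocess_pipeline(lab.voxels, ct, CFG)
    assert np.array_equal(out, lab.voxels)
    assert all(r.removed_by == "none" for r in recs)


def test_three_removals_with_three_distinct_reasons(phantom_pair):
    ct, lab = phantom_pair
    pred = lab.voxels.copy()
    pred[0:3, 0:3, 0:3] = 2                     # border blob (outside abdomen)
    far = np.argwhere((ct.voxels > -600) & (ct.voxels < -50))  # fat ring voxel
    fx, fy, fz = far[len(far) // 2]
    mask = abdomen_mask(ct, CFG)
    det = np.argwhere(mask & (lab.voxels == 0))
    # detached 12-voxel cyst inside the abdomen but far from the pancreas
    dx, dy, dz = max(map(tuple, det),
                     key=lambda v: abs(v[1] - 28))   # extreme y: far from pancreas
    pred[dx, dy - 2:dy + 1, dz - 3:dz + 1] = 2
    # 5-voxel speck touching the pancreas
    panc = np.argwhere(lab.voxels == 1)
    px, py, pz = panc[0]
    speck = np.zeros_like(pred, bool)
    speck[px - 1, py - 5:py, pz] = True
    speck &= (lab.voxels == 0)
    pred[speck] = 2

    out, recs = postprocess_pipeline(pred, ct, CFG)
    reasons = sorted(r.removed_by for r in recs if r.removed_by != "none")
    assert "abdomen" in reasons and "contact" in reasons
    kept = [r for r in recs if r.removed_by == "none"]
    assert len(kept) >= 3                        # the 3 true cysts survive


def test_pipeline_idempotent(phantom_pair):
    ct, lab = phantom_pair
    pred = lab.voxels.copy()
    pred[0:2, 0:2, 0:2] = 2
    once, _ = postprocess_pipeline(pred, ct, CFG)
    twice, _ = postprocess_pipeline(once, ct, CFG)
    assert np.array_equal(once, twice)


def test_filters_never_add_voxels(phantom_pair, rng):
    ct, lab = phantom_pair
    pred = lab.voxels.copy()
    noise = rng.random(pred.shape) < 0.001
    pred[noise & (pred == 0)] = 2
    out, _ = postprocess_pipeline(pred, ct, CFG)
    assert ((out > 0) <= (pred > 0)).all()
    assert ((out == 2) <= (pred == 2)).all()


def test_contact_and_size_filters_match_bruteforce_oracle():
    """Random 20^3 label volumes: surviving cyst voxels after contact+size
    filtering equal the flood-fill + neighbourhood-scan oracle."""
    cfg = PostprocessConfig(min_cyst_voxels=4)
    for seed in range(10):
        rng = np.random.default_rng(seed)
        pred = (rng.random((20, 20, 20)) < 0.08).astype(np.int16) * 2
        pred[rng.random((20, 20, 20)) < 0.05] = 1
        step1, _ = filter_noncontact_cysts(pred, cfg)
        step2, _ = filter_small_components(step1, cfg)
        expect = set()
        for comp in surviving_cysts(pred, cfg.min_cyst_voxels, 26):
            expect |= comp
        got = {tuple(v) for v in np.argwhere(step2 == 2)}
        assert got == expect, f"seed {seed}"
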