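"""Sliding-window coverage/averaging, the TTA transform set, and merging."""

import numpy as np
import pytest
from scipy import ndimage

from pclseg.errors import ConfigurationError, SizeError
from pclseg.inference import (TTATransform, default_tta, sliding_window_infer,
                              tta_predict)
from pclseg.nn import softmax


class ConstModel:
    """Emits a constant per-class logit, ignoring the patch content."""

    def __init__(self, values):
        self.values = np.asarray(values, np.float32)

    def __call__(self, patch):
        out = np.zeros((len(self.values),) + patch.shape, np.float32)
        out += self.values.reshape((-1,) + (1,) * patch.ndim)
        return out


class MeanFilterModel:
    """Translation-equivariant dummy: channel 0 = 3x3x1 box mean, channel 1 = 0."""

    def __call__(self, patch):
        smooth = ndimage.uniform_filter(patch, size=(3, 3, 1), mode="constant")
        return np.stack([smooth, np.zeros_like(patch)])


def test_default_tta_is_the_documented_set():
    tta = default_tta()
    assert len(tta) == 4
    kinds = [(t.kind, t.magnitude) for t in tta]
    assert kinds == [("rotation", 7.0), ("rotation", -11.0),
                     ("translation", 5.0), ("translation", 10.0)]
    rots = [m for k, m in kinds if k == "rotation"]
    assert rots[0] > 0 > rots[1]


@pytest.mark.parametrize("t", default_tta())
def test_transform_inverse_restores_volume(t, rng):
    vol = ndimage.gaussian_filter(rng.normal(size=(48, 48, 6)), 3).astype(np.float32)
    back = t.invert(t.apply(vol))
    interior = (slice(14, 34),) * 2  # away from borders
    # two linear interpolations smooth the field slightly: loose tolerance
    assert np.abs(back[interior] - vol[interior]).max() < 0.05
    assert np.corrcoef(back[interior].ravel(), vol[interior].ravel())[0, 1] > 0.99


def test_unknown_transform_kind_rejected():
    with pytest.raises(ConfigurationError):
        TTATransform("shear", 5.0)


def test_single_patch_inference_equals_model_output(rng):
    vol = rng.normal(size=(16, 16, 8)).astype(np.float32)
    model = ConstModel([0.3, -1.2])
    out = sliding_window_infer(model, vol, (16, 16, 8))
    assert out.shape == (2, 16, 16, 8)
    assert np.allclose(out, model(vol))


def test_constant_model_constant_output_any_stride(rng):
    vol = rng.normal(size=(24, 24, 8)).astype(np.float32)
    model = ConstModel([1.0, 2.0, 3.0])
    for stride in (4, 8, (8, 8, 4)):
        out = sliding_window_infer(model, vol, (16, 16, 8), stride)
        for c, v in enumerate((1.0, 2.0, 3.0)):
            assert np.allclose(out[c], v)


def test_overlap_region_is_arithmetic_mean():
    """Two overlapping patches with patch-index-distinct constants: the
    overlap must hold their mean, verified by hand."""
    calls = []

    def model(patch):
        calls.append(patch)
        v = float(len(calls))        # 1.0 for first patch, 2.0 for second
        return np.full((1,) + patch.shape, v, np.float32)

    vol = np.zeros((6, 4, 4), np.float32)
    out = sliding_window_infer(model, vol, (4, 4, 4), (2, 4, 4))
    assert len(calls) == 2
    assert np.allclose(out[0, :2], 1.0)     # only patch 1
    assert np.allclose(out[0, 2:4], 1.5)    # overlap: mean(1, 2)
    assert np.allclose(out[0, 4:], 2.0)     # only patch 2


def test_stride_exceeding_patch_rejected():
    with pytest.raises(ConfigurationError):
        sliding_window_infer(ConstModel([0.0]), np.zeros((8, 8, 8), np.float32),
                             (4, 4, 4), (6, 4, 4))


def test_volume_smaller_than_patch_rejected():
    with pytest.raises(SizeError):
        sliding_window_infer(ConstModel([0.0]), np.zeros((8, 8, 2), np.float32),
                             (16, 16, 2))


def test_empty_tta_equals_plain_inference(rng):
    vol = rng.normal(size=(16, 16, 4)).astype(np.float32)
    model = MeanFilterModel()
    plain = sliding_window_infer(model, vol, vol.shape)
    probs, labels = tta_predict(model, vol, transforms=[])
    assert np.allclose(probs, softmax(plain, axis=0))
    assert np.array_equal(labels, np.argmax(plain, axis=0))


def test_spatially_constant_model_unaffected_by_tta(rng):
    vol = rng.normal(size=(24, 24, 4)).astype(np.float32)
    model = ConstModel([0.5, -0.5])
    probs_plain, labels_plain = tta_predict(model, vol, transforms=[])
    probs_tta, labels_tta = tta_predict(model, vol)
    assert np.allclose(probs_plain, probs_tta, atol=1e-5)
    assert np.array_equal(labels_plain, labels_tta)


def test_translation_tta_matches_plain_for_equivariant_model(rng):
    """Pure-convolution model + integer translations: merged map equals the
    plain map away from the borders."""
    vol = ndimage.gaussian_filter(rng.normal(size=(32, 32, 4)), 1.5).astype(np.float32)
    model = MeanFilterModel()
    plain = sliding_window_infer(model, vol, vol.shape)
    transforms = [TTATransform("translation", 5.0),
                  TTATransform("translation", 10.0)]
    probs, _ = tta_predict(model, vol, transforms=transforms)
    expect = softmax(plain, axis=0)
    # stay clear of both the validity-mask edge (shift 10 + filter width)
    # and the filter's own constant-padding band
    interior = (slice(None), slice(12, 19), slice(2, 30), slice(None))
    assert np.allclose(probs[interior], expect[interior], atol=1e-4)


def test_merge_invariant_to_transform_order(rng):
    vol = rng.normal(size=(24, 24, 4)).astype(np.float32)
    model = MeanFilterModel()
    fwd = tta_predict(model, vol, transforms=default_tta())[0]
    rev = tta_predict(model, vol, transforms=default_tta()[::-1])[0]
    assert np.allclose(fwd, rev, atol=1e-5)


def test_merged_probabilities_sum_to_one(rng):
    vol = rng.normal(size=(24, 24, 4)).astype(np.float32)
    probs, _ = tta_predict(MeanFilterModel(), vol)
    assert np.allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_padding_does_not_leak_into_average():
    """A voxel-identity model exposes pad contamination: with pad_value far
    below the data range, no merged voxel may ever see it."""

    class LocalModel:                 # logit 0 = the voxel value itself
        def __call__(self, patch):
            return np.stack([patch, np.zeros_like(patch)])

    vol = np.ones((24, 24, 4), np.float32)
    t = TTATransform("translation", 5.0)
    probs, _ = tta_predict(LocalModel(), vol, transforms=[t], pad_value=-100.0)
    # every merged class-0 logit must be exactly 1.0: pad voxels (-100) map
    # back outside the field or are dropped by the validity mask
    expected = np.exp(1.0) / (np.exp(1.0) + 1.0)
    assert np.allclose(probs[0], expected, atol=1e-5)
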