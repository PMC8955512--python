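"""Re-FOV, cropping, spline resampling, and [-1, 1] normalization."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxtrans.preprocess import (FovBox, common_fov, crop_to_fov, denormalize,
                                 normalize, preprocess_pair, resample)
from voxtrans.volume_io import Volume


def _vol(shape, spacing=(1, 1, 1), origin=(0.5, 0.5, 0.5), fill=None, rng=None):
    data = rng.normal(size=shape) if rng is not None else np.full(shape, fill or 0.0)
    return Volume(data=data, spacing=spacing, origin=origin)


class TestCommonFov:
    def test_mr_inside_ct_returns_mr_box(self):
        mr = _vol((100, 100, 100))                         # extent [0,100]^3
        ct = _vol((140, 140, 140), origin=(-19.5, -19.5, -19.5))  # [-20,120]^3
        box = common_fov(mr, ct)
        assert np.allclose(box.lower, 0) and np.allclose(box.upper, 100)

    def test_identical_extents(self):
        mr = _vol((10, 10, 10))
        box = common_fov(mr, _vol((10, 10, 10)))
        assert np.allclose(box.lower, 0) and np.allclose(box.upper, 10)

    def test_protruding_mr_clipped_with_warning(self, caplog):
        # interval-intersection oracle per axis: [−5,5]∩[0,20] = [0,5]
        mr = _vol((10, 10, 10), origin=(-4.5, 0.5, 0.5))   # x extent [-5, 5]
        ct = _vol((20, 20, 20))                            # [0, 20]^3
        with caplog.at_level(logging.WARNING):
            box = common_fov(mr, ct)
        assert np.allclose(box.lower, [0, 0, 0])
        assert np.allclose(box.upper, [5, 10, 10])
        assert any("clipping" in r.message for r in caplog.records)

    def test_disjoint_extents_error(self):
        with pytest.raises(ValueError):
            common_fov(_vol((4, 4, 4)), _vol((4, 4, 4), origin=(100, 100, 100)))


class TestCrop:
    def test_full_extent_identity(self, rng):
        vol = _vol((10, 10, 10), rng=rng)
        lo, hi = vol.extent()
        out = crop_to_fov(vol, FovBox(tuple(lo), tuple(hi)))
        np.testing.assert_array_equal(out.data, vol.data)
        assert out.origin == vol.origin

    def test_half_extent_keeps_five_columns(self, rng):
        vol = _vol((10, 10, 10), rng=rng)
        out = crop_to_fov(vol, FovBox((0, 0, 0), (5, 10, 10)))
        assert out.shape == (5, 10, 10)
        np.testing.assert_array_equal(out.data, vol.data[:5])

    def test_matches_brute_force_center_membership(self, rng):
        """Oracle: count voxel centers inside the box by direct enumeration."""
        vol = _vol((7, 6, 5), spacing=(1.3, 0.9, 2.1), origin=(0.2, -1.0, 3.0), rng=rng)
        box = FovBox((1.0, -0.5, 3.5), (6.5, 3.1, 9.0))
        kept = []
        for i in range(7):
            for j in range(6):
                for k in range(5):
                    c = (0.2 + i * 1.3, -1.0 + j * 0.9, 3.0 + k * 2.1)
                    if all(lo <= cc < hi for cc, lo, hi in zip(c, box.lower, box.upper)):
                        kept.append((i, j, k))
        out = crop_to_fov(vol, box)
        ii, jj, kk = zip(*kept)
        expected_shape = (max(ii) - min(ii) + 1, max(jj) - min(jj) + 1,
                          max(kk) - min(kk) + 1)
        assert out.shape == expected_shape
        np.testing.assert_array_equal(
            out.data, vol.data[min(ii):max(ii) + 1, min(jj):max(jj) + 1,
                               min(kk):max(kk) + 1])

    def test_disjoint_box_error(self, rng):
        with pytest.raises(ValueError):
            crop_to_fov(_vol((4, 4, 4), rng=rng), FovBox((50, 50, 50), (60, 60, 60)))


class TestResample:
    def test_identity_grid(self, rng):
        vol = _vol((12, 10, 8), spacing=(1.5, 2.0, 2.5), rng=rng)
        out = resample(vol, (12, 10, 8))
        assert np.allclose(out.data, vol.data, atol=1e-5)
        assert np.allclose(out.spacing, vol.spacing)

    def test_linear_ramp_upsampled_exactly(self):
        """Order-3 splines reproduce polynomials up to cubic: a linear ramp
        doubled in resolution stays the analytic ramp away from the volume
        boundary (edge clamping perturbs a shrinking band near the faces)."""
        shape = (16, 8, 8)
        x = np.arange(shape[0])[:, None, None] * np.ones(shape)
        vol = Volume(data=x, spacing=(1, 1, 1), origin=(0.5, 0.5, 0.5))
        out = resample(vol, (32, 8, 8))
        # new centers at physical 0.25 + 0.5*i -> input index (0.25+0.5*i-0.5)
        expected = 0.25 + 0.5 * np.arange(32) - 0.5
        interior = slice(12, 20)
        assert np.allclose(out.data[interior, 4, 4], expected[interior], atol=1e-6)

    def test_degenerate_target_error(self, rng):
        with pytest.raises(ValueError):
            resample(_vol((8, 8, 8), rng=rng), (1, 8, 8))


class TestNormalize:
    def test_three_point_symmetric_case(self):
        vol = Volume(data=np.array([0.0, 5.0, 10.0]).reshape(3, 1, 1))
        out, _ = normalize(vol)
        np.testing.assert_allclose(out.data.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_range_and_inversion(self, seed):
        """Any non-constant image maps onto exactly [-1, 1] and the stored
        record inverts the map to 1e-6."""
        data = np.random.default_rng(seed).normal(10.0, 5.0, size=(6, 5, 4))
        vol = Volume(data=data)
        out, rec = normalize(vol)
        assert abs(out.data.min() + 1.0) < 1e-9
        assert abs(out.data.max() - 1.0) < 1e-9
        back = denormalize(out, rec)
        assert np.allclose(back.data, data, atol=1e-6)

    def test_constant_image_error(self):
        with pytest.raises(ValueError):
            normalize(Volume(data=np.full((4, 4, 4), 3.0)))


class TestPreprocessPair:
    def test_phantom_pair_invariants(self, phantom_dataset):
        raw = phantom_dataset[0]
        sample = preprocess_pair(raw.mr, raw.ct, (64, 64, 32))
        sample.validate_grids()
        for vol in (sample.mr, sample.ct):
            assert vol.shape == (64, 64, 32)
            assert abs(vol.data.min() + 1.0) < 1e-6
            assert abs(vol.data.max() - 1.0) < 1e-6

    def test_geometry_idempotent(self, phantom_dataset):
        raw = phantom_dataset[1]
        once = preprocess_pair(raw.mr, raw.ct, (32, 32, 16))
        twice = preprocess_pair(once.mr, once.ct, (32, 32, 16))
        assert np.allclose(once.mr.spacing, twice.mr.spacing, atol=1e-9)
        assert np.allclose(once.mr.origin, twice.mr.origin, atol=1e-9)

    def test_already_matched_pair_geometry_unchanged(self, rng):
        mr = _vol((16, 16, 8), spacing=(2, 2, 4), rng=rng)
        ct = _vol((16, 16, 8), spacing=(2, 2, 4), rng=rng)
        out = preprocess_pair(mr, ct, (16, 16, 8))
        assert np.allclose(out.mr.spacing, mr.spacing)
        assert np.allclose(out.mr.origin, mr.origin)

    def test_production_target_shape(self, rng):
        """Resampling a pair to the production 200 x 200 x 128 grid."""
        mr = _vol((40, 40, 26), spacing=(4, 4, 4), rng=rng)
        ct = _vol((50, 50, 32), spacing=(4, 4, 4), origin=(-19.5, -19.5, -11.5), rng=rng)
        out = preprocess_pair(mr, ct, (200, 200, 128))
        assert out.mr.shape == (200, 200, 128)
        assert out.ct.shape == (200, 200, 128)
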