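"""Sliding-window blending identities and the non-learned benchmarks."""

import numpy as np
import pytest

from bonesr.inference import (
    ConventionalParams,
    SlidingWindowConfig,
    conventional_enhance,
    gaussian_weight_map,
    orthogonal_average,
    sliding_window_sr,
    tricubic_upscale,
    upscale_slice_axis,
)
from bonesr.volio import Volume


def _vol(data, voxel=200.0):
    return Volume(data=np.clip(data, 0, 1).astype(np.float32),
                  voxel_size_um=voxel)


class ConstantStub:
    """Model stub returning a constant tile."""

    dims, upscale = 2, 4

    def __init__(self, value=0.5, dims=2):
        self.value, self.dims = value, dims

    def predict(self, batch):
        n, _, *spatial = batch.shape
        return np.full((n, 1, *[4 * s for s in spatial]), self.value, np.float32)


class OracleStub:
    """Returns the true high-resolution tile for each window position."""

    dims, upscale = 2, 4
    wants_positions = True

    def __init__(self, hr_2d):
        self.hr = hr_2d

    def predict(self, batch, origins):
        out = []
        for (y, x) in origins:
            out.append(self.hr[4 * y:4 * y + 64, 4 * x:4 * x + 64])
        return np.stack(out)[:, None]


class NearestStub:
    """Nearest-neighbour x4 of the input tile."""

    dims, upscale = 2, 4

    def predict(self, batch):
        return np.repeat(np.repeat(batch, 4, axis=-2), 4, axis=-1)


class TestWeightMap:
    def test_centre_is_one(self):
        w = gaussian_weight_map(64, 16.0)
        assert w.max() == pytest.approx(1.0)
        assert w[31, 31] == w.max() or w[32, 32] == w.max()

    def test_symmetric_under_flips(self):
        w = gaussian_weight_map(64, 16.0)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)
        np.testing.assert_allclose(w, w[:, ::-1], atol=1e-15)
        np.testing.assert_allclose(w, w.T, atol=1e-15)

    def test_corner_to_centre_ratio_closed_form(self):
        w = gaussian_weight_map(64, 16.0)
        expected = np.exp(-(2 * 31.5 ** 2) / (2 * 16.0 ** 2))
        centre = np.exp(-(2 * 0.5 ** 2) / (2 * 16.0 ** 2))
        assert w[0, 0] / w.max() == pytest.approx(expected / centre, rel=1e-6)

    def test_strictly_positive(self):
        assert gaussian_weight_map(64, 2.0).min() >= 1e-4


class TestSlidingWindow:
    def test_constant_stub_gives_exact_constant(self, rng):
        vol = _vol(rng.random((3, 20, 26)))
        out = sliding_window_sr(vol, ConstantStub(0.5))
        assert out.shape == (3, 80, 104)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)

    def test_no_overlap_equals_overlap_on_constant(self):
        vol = _vol(np.full((1, 32, 32), 0.25))
        a = sliding_window_sr(vol, ConstantStub(0.25),
                              SlidingWindowConfig(step_lr=16))
        b = sliding_window_sr(vol, ConstantStub(0.25),
                              SlidingWindowConfig(step_lr=8))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_perfect_oracle_reconstructs_exactly(self, rng):
        lr = rng.random((2, 24, 32)).astype(np.float32)
        hr = rng.random((2, 96, 128)).astype(np.float32)
        vol = _vol(lr)
        outs = []
        for z in range(2):
            stub = OracleStub(hr[z])
            outs.append(sliding_window_sr(
                _vol(lr[z][None]), stub).data[0])
        np.testing.assert_allclose(np.stack(outs), hr, atol=1e-6)

    def test_nearest_stub_blends_stripes_sharply(self):
        stripe = np.zeros((1, 16, 32), np.float32)
        stripe[:, :, 16:] = 1.0
        out = sliding_window_sr(_vol(stripe), NearestStub()).data[0]
        # stripes at 4x width; transition confined to about one output pixel
        assert np.all(out[:, :62] < 0.01)
        assert np.all(out[:, 66:] > 0.99)

    def test_blend_is_convex_combination(self, rng):
        vol = _vol(rng.random((1, 24, 24)))
        out = sliding_window_sr(vol, NearestStub())
        assert out.data.min() >= vol.data.min() - 1e-9
        assert out.data.max() <= vol.data.max() + 1e-9

    def test_plane_selection_and_3d_mismatch(self, rng):
        vol = _vol(rng.random((4, 16, 16)))
        with pytest.raises(ValueError):
            sliding_window_sr(vol, ConstantStub(dims=4))


class TestOrthogonalAverage:
    def test_constant_stub_constant(self):
        vol = _vol(np.full((8, 8, 8), 0.5))
        out = orthogonal_average(vol, ConstantStub(0.5))
        assert out.shape == (32, 32, 32)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-7)

    def test_single_plane_consistency(self, rng):
        vol = _vol(rng.random((4, 16, 16)))
        by_slices = np.stack([
            sliding_window_sr(_vol(vol.data[z][None]), NearestStub()).data[0]
            for z in range(4)
        ])
        direct = sliding_window_sr(vol, NearestStub(),
                                   SlidingWindowConfig(plane="axial"))
        np.testing.assert_allclose(direct.data, by_slices, atol=1e-12)

    def test_3d_model_rejected(self, rng):
        vol = _vol(rng.random((8, 8, 8)))
        with pytest.raises(ValueError):
            orthogonal_average(vol, ConstantStub(dims=3))


class TestTricubic:
    def test_constant_preserved(self):
        out = tricubic_upscale(_vol(np.full((4, 4, 4), 0.3)))
        assert out.shape == (16, 16, 16)
        np.testing.assert_allclose(out.data, 0.3, atol=1e-6)

    def test_linear_ramp_reproduced(self):
        n = 32
        ramp = np.tile(np.linspace(0.1, 0.9, n)[None, None, :], (4, 4, 1))
        out = tricubic_upscale(_vol(ramp)).data
        # cubic interpolation reproduces degree-1 polynomials away from the
        # borders (the spline boundary condition decays ~0.27 per input cell);
        # output sample i sits at input coordinate (i + 0.5)/4 - 0.5
        coords = (np.arange(4 * n) + 0.5) / 4 - 0.5
        expected = 0.1 + coords * (0.8 / (n - 1))
        np.testing.assert_allclose(out[8, 8, 48:-48], expected[48:-48], atol=1e-6)

    def test_voxel_size_scaled(self):
        out = tricubic_upscale(_vol(np.random.default_rng(0).random((4, 4, 4)), 200.0))
        np.testing.assert_allclose(out.voxel_size_um, 50.0)


class TestConventional:
    def test_constant_maps_to_zero_by_degenerate_stretch(self):
        out = conventional_enhance(_vol(np.full((6, 6, 6), 0.4)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_noise_suppressed_within_regions(self, rng):
        step = np.zeros((8, 16, 16))
        step[:, :, 8:] = 0.8
        noisy = np.clip(step + rng.normal(0, 0.05, step.shape), 0, 1)
        out = conventional_enhance(_vol(noisy)).data
        pre = noisy[:, :, :6].var()
        post = out[:, :, :6].var()
        assert post < pre

    def test_median_removes_salt_and_pepper(self, rng):
        from scipy.ndimage import median_filter

        clean = np.zeros((8, 8, 8))
        noisy = clean.copy()
        idx = rng.integers(1, 7, size=(10, 3))
        noisy[tuple(idx.T)] = 1.0
        out = median_filter(noisy, size=3)
        np.testing.assert_array_equal(out, clean)


class TestSliceAxisUpscale:
    def test_axis_extent_and_voxel(self, rng):
        vol = _vol(rng.random((4, 8, 8)), 200.0)
        out = upscale_slice_axis(vol, axis=0)
        assert out.shape == (16, 8, 8)
        np.testing.assert_allclose(out.voxel_size_um, [50.0, 200.0, 200.0])
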