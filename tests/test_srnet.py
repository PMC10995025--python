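"""Network contracts and loss-function oracles."""

import numpy as np
import pytest

from bonesr import srnet


def _tiny_cfg(dims=2, seed=0):
    return srnet.SRNetworkConfig(dims=dims, n_residual_blocks=1,
                                 base_channels=4, seed=seed)


class TestNetwork:
    @pytest.mark.parametrize("dims,in_shape,out_shape", [
        (2, (1, 1, 16, 16), (1, 1, 64, 64)),
        (3, (1, 1, 8, 8, 8), (1, 1, 32, 32, 32)),
    ])
    def test_output_is_4x_input(self, dims, in_shape, out_shape, rng):
        model = srnet.build_network(_tiny_cfg(dims))
        out = model.forward(rng.random(in_shape).astype(np.float32))
        assert out.shape == out_shape

    def test_seeded_init_reproducible(self):
        a = srnet.build_network(_tiny_cfg(seed=3))
        b = srnet.build_network(_tiny_cfg(seed=3))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = srnet.build_network(_tiny_cfg(seed=4))
        assert any(not np.array_equal(pa.value, pc.value)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_parameter_count_pure_function_of_config(self):
        n1 = srnet.build_network(_tiny_cfg()).n_parameters()
        n2 = srnet.build_network(_tiny_cfg(seed=9)).n_parameters()
        assert n1 == n2
        bigger = srnet.SRNetworkConfig(dims=2, n_residual_blocks=2, base_channels=8)
        assert srnet.build_network(bigger).n_parameters() > n1

    def test_constant_input_gives_constant_output(self):
        model = srnet.build_network(_tiny_cfg())
        out = model.forward(np.full((1, 1, 16, 16), 0.37, np.float32))
        assert out.max() - out.min() < 1e-5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            srnet.SRNetworkConfig(dims=4)
        with pytest.raises(ValueError):
            srnet.SRNetworkConfig(n_residual_blocks=0)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = srnet.build_network(_tiny_cfg(seed=5), recipe="structure")
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        expected = model.predict(x)
        srnet.save_model(model, tmp_path / "m.npz")
        loaded = srnet.load_model(tmp_path / "m.npz")
        assert loaded.recipe == "structure"
        np.testing.assert_allclose(loaded.predict(x), expected, atol=1e-7)


class TestPixelLosses:
    def test_identical_inputs_zero(self, rng):
        x = rng.random((4, 4))
        assert srnet.mse_loss(x, x) == 0.0
        assert srnet.mae_loss(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random((8, 8))
        assert srnet.mse_loss(x + 0.1, x) == pytest.approx(0.01, rel=1e-9)
        assert srnet.mae_loss(x + 0.1, x) == pytest.approx(0.1, rel=1e-9)

    def test_matches_hand_summed_values(self, rng):
        p, t = rng.random((4, 4)), rng.random((4, 4))
        by_hand_mse = sum((p[i, j] - t[i, j]) ** 2 for i in range(4) for j in range(4)) / 16
        by_hand_mae = sum(abs(p[i, j] - t[i, j]) for i in range(4) for j in range(4)) / 16
        assert srnet.mse_loss(p, t) == pytest.approx(by_hand_mse, rel=1e-12)
        assert srnet.mae_loss(p, t) == pytest.approx(by_hand_mae, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            srnet.mse_loss(rng.random((4, 4)), rng.random((4, 5)))


class TestTVLoss:
    def test_constant_is_zero(self):
        assert srnet.tv_loss(np.full((6, 6), 0.5)) == 0.0

    def test_ramp_normalization_constant(self):
        # 1x4 ramp 0,1,2,3 -> mean absolute forward difference 1
        assert srnet.tv_loss(np.array([[0.0, 1.0, 2.0, 3.0]])) == pytest.approx(1.0)

    def test_blur_reduces_tv_of_checkerboard(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        blurred = np.full((8, 8), 0.5)
        assert srnet.tv_loss(board.astype(float)) > srnet.tv_loss(blurred)


class TestSSIM:
    def test_identical_images(self, rng):
        x = rng.random((16, 16))
        assert srnet.ssim(x, x) == pytest.approx(1.0, abs=1e-12)
        assert srnet.structure_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_contrast_inversion_negative(self):
        x = np.tile(np.linspace(0, 1, 16), (16, 1))
        assert srnet.ssim(x, 1.0 - x) < 0.0

    def test_symmetric(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert srnet.ssim(a, b) == pytest.approx(srnet.ssim(b, a), rel=1e-12)

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            srnet.ssim(rng.random((8, 8)), rng.random((8, 8)))

    def test_agrees_with_reference_implementation(self, rng):
        from skimage.metrics import structural_similarity

        a = rng.random((48, 48))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        ref = structural_similarity(a, b, win_size=11, gaussian_weights=True,
                                    sigma=1.5, data_range=1.0,
                                    use_sample_covariance=False)
        # border handling differs (reflect vs crop); interior dominates
        assert srnet.ssim(a, b) == pytest.approx(ref, abs=5e-3)

    def test_gradient_matches_finite_differences(self, rng):
        a, b = rng.random((14, 14)), rng.random((14, 14))
        grad = srnet._structure_grad(a, b, window_size=7)
        eps = 1e-4
        for idx in [(0, 0), (3, 9), (13, 13), (7, 7)]:
            ap, am = a.copy(), a.copy()
            ap[idx] += eps
            am[idx] -= eps
            fd = (srnet.structure_loss(ap, b, window_size=7)
                  - srnet.structure_loss(am, b, window_size=7)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=1e-6)


class TestPerceptualLoss:
    def test_identical_inputs_zero(self, rng):
        fx = srnet.FeatureExtractor(seed=0)
        x = rng.random((10, 10)).astype(np.float32)
        assert srnet.perceptual_loss(x, x, fx) == 0.0

    def test_nonnegative_and_deterministic(self, rng):
        fx1 = srnet.FeatureExtractor(seed=2)
        fx2 = srnet.FeatureExtractor(seed=2)
        p, t = rng.random((12, 12)), rng.random((12, 12))
        l1 = srnet.perceptual_loss(p, t, fx1)
        l2 = srnet.perceptual_loss(p, t, fx2)
        assert l1 > 0
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_pretrained_backend_unavailable_names_fallback(self):
        with pytest.raises(RuntimeError, match="seeded_random_conv"):
            srnet.FeatureExtractor(backend="pretrained_vgg16")


class TestCompositeLoss:
    def test_baseline_on_identical_pair_reduces_to_tv_term(self, rng):
        t = rng.random((16, 16))
        expected = 0.2 * srnet.tv_loss(t)
        assert srnet.composite_loss("baseline", t, t) == pytest.approx(expected)

    def test_structure_on_identical_pair_is_zero(self, rng):
        t = rng.random((16, 16))
        assert srnet.composite_loss("structure", t, t) == pytest.approx(0.0, abs=1e-12)

    def test_baseline_equals_weighted_term_calls(self, rng):
        p, t = rng.random((4, 4)), rng.random((4, 4))
        expected = 0.8 * srnet.mse_loss(p, t) + 0.2 * srnet.tv_loss(p)
        assert srnet.composite_loss("baseline", p, t) == pytest.approx(expected, rel=1e-12)

    def test_visual_requires_extractor(self, rng):
        p, t = rng.random((12, 12)), rng.random((12, 12))
        with pytest.raises(ValueError):
            srnet.composite_loss("visual", p, t)
        fx = srnet.FeatureExtractor(seed=0)
        expected = (0.1 * srnet.mae_loss(p, t) + 1.0 * srnet.tv_loss(p)
                    + 1.0 * srnet.perceptual_loss(p, t, fx))
        assert srnet.composite_loss("visual", p, t, fx=fx) == pytest.approx(expected, rel=1e-9)

    def test_batch_of_identical_items_equals_single_item(self, rng):
        p, t = rng.random((16, 16)), rng.random((16, 16))
        batch_p = np.stack([p] * 3)[:, None]
        batch_t = np.stack([t] * 3)[:, None]
        single = srnet.composite_loss("structure", p[None, None], t[None, None])
        batch = srnet.composite_loss("structure", batch_p, batch_t)
        assert batch == pytest.approx(single, rel=1e-9)
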