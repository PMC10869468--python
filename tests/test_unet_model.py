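import numpy as np
import pytest

import pituseg.nn as nn
from pituseg.evaluation import dice_iou
from pituseg.model import UNet3DSegmenter, UNetConfig, build_unet, predict_patch, soft_dice_loss


class TestArchitectureContracts:
    def test_output_shape_and_range(self, rng):
        net = build_unet(UNetConfig(depth=3, base_filters=4), seed=0)
        x = rng.normal(size=(2, 1, 16, 16, 16)).astype(np.float32)
        p = net.forward(x)
        assert p.shape == (2, 1, 16, 16, 16)
        assert p.min() > 0 and p.max() < 1

    def test_constant_output_on_zero_input(self):
        net = build_unet(UNetConfig(depth=3, base_filters=4), seed=1)
        p = net.forward(np.zeros((1, 1, 8, 8, 8), dtype=np.float32))
        assert np.allclose(p, p.flat[0])

    def test_indivisible_input_rejected(self):
        net = build_unet(UNetConfig(depth=3, base_filters=2), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 10, 10, 10), dtype=np.float32))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=1)
        with pytest.raises(ValueError):
            UNetConfig(depth=7)  # 32 not divisible by 2**6
        with pytest.raises(ValueError):
            UNetConfig(threshold=1.5)
        with pytest.raises(ValueError):
            UNetConfig(loss_smooth=0.0)

    @pytest.mark.parametrize("depth,base", [(2, 4), (3, 8)])
    def test_parameter_count_closed_form(self, depth, base):
        """Total parameter count equals the layer-by-layer closed form."""
        net = build_unet(UNetConfig(depth=depth, base_filters=base), seed=0)
        widths = [base * 2**i for i in range(depth)]

        def conv(cin, cout, k=3):
            return cout * (cin * k**3 + 1)

        def block(cin, cout):
            return conv(cin, cout) + conv(cout, cout) + 2 * 2 * cout  # + 2 instance norms

        expected = 0
        c = 1
        for w in widths:
            expected += block(c, w)
            c = w
        for i in range(depth - 2, -1, -1):
            expected += widths[i + 1] * widths[i] * 8 + widths[i]  # transposed conv
            expected += block(2 * widths[i], widths[i])
        expected += conv(widths[0], 1, k=1)
        assert net.n_parameters == expected


class TestSoftDiceLoss:
    def test_perfect_overlap_is_zero(self, rng):
        t = (rng.uniform(size=(8, 8, 8)) > 0.7).astype(float)
        assert soft_dice_loss(t, t, smooth=1e-9) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_masks_approach_one(self):
        p = np.zeros((6, 6, 6))
        t = np.zeros((6, 6, 6))
        p[0, 0, 0] = 1
        t[5, 5, 5] = 1
        assert soft_dice_loss(p, t, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_arithmetic_oracle_eight_voxels(self):
        """p = 0.5 on 8 voxels, t with 4 ones, eps = 1:
        1 - (2*2 + 1)/(4 + 4 + 1) = 4/9."""
        p = np.full((2, 2, 2), 0.5)
        t = np.zeros((2, 2, 2))
        t.flat[:4] = 1
        assert soft_dice_loss(p, t, smooth=1.0) == pytest.approx(1 - 5 / 9, abs=1e-12)

    def test_matches_hard_dice_on_binary_inputs(self, rng):
        """For binary p and eps -> 0 the loss equals 1 - DICE from the
        evaluation module on 50 random pairs."""
        for _ in range(50):
            p = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(float)
            t = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(float)
            if p.sum() + t.sum() == 0:
                continue
            dice, _ = dice_iou(p.astype(np.uint8), t.astype(np.uint8))
            assert soft_dice_loss(p, t, smooth=1e-9) == pytest.approx(1 - dice, abs=1e-6)

    def test_range_and_shape_check(self, rng):
        p = rng.uniform(size=(4, 4, 4))
        t = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(float)
        assert 0.0 <= soft_dice_loss(p, t) <= 1.0
        with pytest.raises(ValueError, match="mismatch"):
            soft_dice_loss(p, t[:2])

    def test_gradient_matches_numerical(self, rng):
        p = rng.uniform(0.05, 0.95, size=(4, 4, 4))
        t = (rng.uniform(size=(4, 4, 4)) > 0.6).astype(float)
        g = nn.soft_dice_loss_grad(p, t, smooth=1.0)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            p2 = p.copy()
            p2[idx] += eps
            num = (nn.soft_dice_loss(p2, t) - nn.soft_dice_loss(p, t)) / eps
            assert g[idx] == pytest.approx(num, rel=1e-4)


class TestBackprop:
    def test_network_gradients_match_numerical(self, rng, monkeypatch):
        """Analytic backprop through the full U-Net agrees with central
        finite differences (double precision)."""
        monkeypatch.setattr(nn, "_DT", np.float64)
        net = nn.UNet3D(depth=2, base_filters=2, seed=3)
        for v in net.parameters().values():
            v[...] = v.astype(np.float64)
        x = rng.normal(size=(1, 1, 4, 4, 4))
        t = (rng.uniform(size=(1, 1, 4, 4, 4)) > 0.7).astype(float)
        p = net.forward(x)
        net.backward(nn.soft_dice_loss_grad(p, t))
        grads = {k: v.copy() for k, v in net.gradients().items()}
        params = net.parameters()
        check_rng = np.random.default_rng(0)
        for key, arr in params.items():
            idx = tuple(check_rng.integers(s) for s in arr.shape)
            eps = 1e-6
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = nn.soft_dice_loss(net.forward(x), t)
            arr[idx] = orig - eps
            lm = nn.soft_dice_loss(net.forward(x), t)
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key].reshape(arr.shape)[idx]
            assert ana == pytest.approx(num, rel=1e-3, abs=1e-9), key


class TestEstimator:
    def test_inference_deterministic(self, rng):
        est = UNet3DSegmenter(depth=2, base_filters=2, epochs=1, random_state=0)
        X = rng.normal(size=(3, 8, 8, 8))
        y = (rng.uniform(size=(3, 8, 8, 8)) > 0.9).astype(np.uint8)
        est.fit(X, y)
        np.testing.assert_array_equal(est.predict_proba(X), est.predict_proba(X))

    def test_empty_binary_mask_below_threshold(self, rng):
        est = UNet3DSegmenter(depth=2, base_filters=2, epochs=1, threshold=0.999999)
        X = rng.normal(size=(2, 8, 8, 8))
        y = np.zeros_like(X, dtype=np.uint8)
        est.fit(X, y)
        assert est.predict(X).sum() == 0

    def test_sklearn_params_round_trip(self):
        est = UNet3DSegmenter(base_filters=4)
        params = est.get_params()
        assert params["base_filters"] == 4
        clone = UNet3DSegmenter(**params).set_params(epochs=3)
        assert clone.get_params()["epochs"] == 3

    def test_checkpoint_round_trip(self, tmp_path, rng):
        est = UNet3DSegmenter(depth=2, base_filters=2, epochs=1, random_state=1)
        X = rng.normal(size=(2, 8, 8, 8))
        y = (rng.uniform(size=(2, 8, 8, 8)) > 0.9).astype(np.uint8)
        est.fit(X, y)
        est.save(tmp_path / "ckpt.npz")
        loaded = UNet3DSegmenter.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(loaded.predict_proba(X), est.predict_proba(X))

    def test_predict_patch_wrapper(self, rng):
        est = UNet3DSegmenter(depth=2, base_filters=2, epochs=1)
        X = rng.normal(size=(2, 8, 8, 8))
        y = (rng.uniform(size=(2, 8, 8, 8)) > 0.9).astype(np.uint8)
        est.fit(X, y)
        pred = predict_patch(est, X[0])
        assert pred.probabilities.shape == (8, 8, 8)
        np.testing.assert_array_equal(pred.binary, (pred.probabilities > 0.5).astype(np.uint8))
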