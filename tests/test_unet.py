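"""Architecture contracts, loss oracle, receptive field, covariance."""

import numpy as np
import pytest

from localbrainage.unet import (
    ArchitectureSpec,
    ConvChain,
    LossConfig,
    build_network,
    composite_loss,
    load_checkpoint,
    loss_gradients,
    measure_receptive_field,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def net():
    return build_network(ArchitectureSpec(base_channels=2), seed=0, output_bias=50.0)


class TestSpecValidation:
    def test_defaults_are_the_published_model(self):
        spec = ArchitectureSpec()
        assert spec.base_channels == 64
        assert spec.n_convs == 10
        assert spec.receptive_field_side == 23

    def test_kernel_fixed(self):
        with pytest.raises(ValueError, match="3x3x3"):
            ArchitectureSpec(conv_kernel=5)

    def test_aux_heads_tied_to_scales(self):
        with pytest.raises(ValueError, match="aux_heads"):
            ArchitectureSpec(aux_heads=3)

    def test_broken_spatial_contract(self):
        with pytest.raises(ValueError, match="spatial contract"):
            ArchitectureSpec(convs_per_scale=5)  # 25 valid convs shrink below 12


class TestShapeContract:
    def test_52_in_12_out_with_two_aux(self, net):
        x = np.random.default_rng(0).random((52, 52, 52, 2), dtype=np.float32)
        voxel, aux = net.forward(x)
        assert voxel.shape == (12, 12, 12)
        assert len(aux) == 2
        assert all(np.isscalar(a) or np.ndim(a) == 0 for a in aux)

    def test_channel_doubling_per_scale(self, net):
        assert net.level_channels == [2, 4]
        assert net.bottleneck[0][0].W.shape[1] == 8

    def test_all_zero_weights_output_equals_bias(self, net):
        z = net.clone()
        for p in z.parameters():
            p[...] = 0.0
        z.final.b[0] = 33.0
        for h in z.aux:
            h.b[0] = 33.0
        voxel, aux = z.forward(np.random.rand(52, 52, 52, 2).astype(np.float32))
        np.testing.assert_allclose(voxel, 33.0, atol=1e-5)
        np.testing.assert_allclose(aux, 33.0, atol=1e-5)

    def test_wrong_channel_count_rejected(self, net):
        with pytest.raises(ValueError, match="input"):
            net.forward(np.zeros((52, 52, 52, 3), dtype=np.float32))


class TestCompositeLoss:
    def _brute_force(self, voxel, aux, ages, a1, a2):
        # independent re-statement: explicit loops, no broadcasting
        total = 0.0
        for i in range(len(ages)):
            for v in np.asarray(voxel[i]).ravel():
                total += abs(ages[i] - v)
            total += a1 * abs(ages[i] - aux[i][0]) + a2 * abs(ages[i] - aux[i][1])
        return total

    def test_matches_brute_force_on_random_tensors(self, rng):
        cfg = LossConfig(alpha_1=0.7, alpha_2=0.3, decay_iterations=100)
        for it in (0, 37, 100):
            voxel = rng.normal(50, 10, size=(3, 12, 12, 12))
            aux = rng.normal(50, 10, size=(3, 2))
            ages = rng.uniform(18, 90, size=3)
            scale = max(0.0, 1.0 - it / 100)
            expected = self._brute_force(voxel, aux, ages, 0.7 * scale, 0.3 * scale)
            got = composite_loss((voxel, aux), ages, cfg, it)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_perfect_predictions_zero(self):
        voxel = np.full((12, 12, 12), 40.0)
        assert composite_loss((voxel, [40.0, 40.0]), 40.0, LossConfig(), 0) == 0.0

    def test_alpha_zero_reduces_to_voxel_mae_sum(self):
        voxel = np.full((12, 12, 12), 40.0)
        voxel[0, 0, 0] = 42.0
        cfg = LossConfig(alpha_1=0.0, alpha_2=0.0)
        assert composite_loss((voxel, [0.0, 99.0]), 40.0, cfg, 0) == pytest.approx(2.0)

    def test_aux_ignored_after_decay_horizon(self, rng):
        cfg = LossConfig()
        voxel = rng.normal(50, 5, size=(12, 12, 12))
        a = composite_loss((voxel, [10.0, 20.0]), 50.0, cfg, 50_000)
        b = composite_loss((voxel, [70.0, -5.0]), 50.0, cfg, 50_000)
        assert a == b
        assert cfg.alphas(50_000).tolist() == [0.0, 0.0]
        assert cfg.alphas(25_000).tolist() == [0.5, 0.5]

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            LossConfig(alpha_1=-1.0)


class TestReceptiveField:
    def test_full_architecture_measures_23(self, net):
        assert measure_receptive_field(net) == 23

    @pytest.mark.parametrize("n_convs,expected", [(1, 3), (2, 5), (4, 9)])
    def test_conv_chain_grows_by_two_per_conv(self, n_convs, expected):
        assert measure_receptive_field(ConvChain(n_convs, seed=0)) == expected


def test_translation_covariance(net):
    """Shifting block content by 12 voxels shifts the prediction block."""
    rng = np.random.default_rng(7)
    content = rng.random((12, 12, 12, 2), dtype=np.float32)
    x1 = np.zeros((64, 64, 64, 2), dtype=np.float32)
    x2 = np.zeros((64, 64, 64, 2), dtype=np.float32)
    x1[22:34, 22:34, 22:34] = content
    x2[34:46, 22:34, 22:34] = content  # shifted +12 along axis 0
    y1, _ = net.forward(x1)  # output side 24, covers input voxels 20..43
    y2, _ = net.forward(x2)
    np.testing.assert_allclose(y2[12:24], y1[0:12], atol=1e-4)


class TestLayerGradients:
    """Central finite differences against each layer's analytic backward.

    Checked per layer at small sizes, where float32 truncation stays well
    below the tolerance; a whole-network directional check would drown the
    comparison in accumulated rounding noise.
    """

    @staticmethod
    def _check(layer, x, seed=1):
        from localbrainage import unet as U

        y = layer.forward(x)
        dy = np.random.default_rng(seed).standard_normal(np.shape(y)).astype(np.float32)
        if np.isscalar(y):
            dy = float(dy)
        for g in layer.grads:
            g[...] = 0.0
        dx = layer.backward(dy)

        def probe():
            out = layer.forward(x)
            return float(out * dy) if np.isscalar(out) else float((out * dy).sum())

        eps = 1e-3
        # input gradient
        d = np.random.default_rng(seed + 1).standard_normal(x.shape).astype(np.float32) * 0.1
        x += eps * d
        lp = probe()
        x -= 2 * eps * d
        lm = probe()
        x += eps * d
        num, ana = (lp - lm) / (2 * eps), float((dx * d).sum())
        assert num == pytest.approx(ana, rel=5e-3, abs=2e-3)
        # parameter gradients
        for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
            dp = np.random.default_rng(seed + 2 + pi).standard_normal(p.shape).astype(
                np.float32
            ) * 0.1
            p += eps * dp
            lp = probe()
            p -= 2 * eps * dp
            lm = probe()
            p += eps * dp
            num, ana = (lp - lm) / (2 * eps), float((g * dp).sum())
            assert num == pytest.approx(ana, rel=5e-3, abs=2e-3)

    @pytest.mark.parametrize(
        "layer_name",
        ["conv3", "lrelu", "squeeze_excite", "avgpool", "upsample", "aux_head", "conv1"],
    )
    def test_layer_backward_matches_finite_difference(self, layer_name):
        from localbrainage import unet as U

        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8, 8, 3)).astype(np.float32)
        layer = {
            "conv3": lambda: U._Conv3(3, 4, rng),
            "lrelu": lambda: U._LeakyReLU(0.2),
            "squeeze_excite": lambda: U._SqueezeExcite(3, 1, rng),
            # (gate bias re-centred below: finite differences are ill-
            # conditioned on the saturated branch of the sigmoid)
            "avgpool": U._AvgPool2Stride1,
            "upsample": U._UpsampleRepeat,
            "aux_head": lambda: U._AuxHead(3, rng, 0.5),
            "conv1": lambda: U._Conv1(3, rng, 0.2),
        }[layer_name]()
        if layer_name == "squeeze_excite":
            # keep both nonlinearities away from their kink/saturation so
            # central differences are well conditioned
            layer.b1[...] = 0.3
            layer.b2[...] = 0.5
        self._check(layer, x)

    def test_concat_crop_backward(self):
        from localbrainage import unet as U

        rng = np.random.default_rng(0)
        cat = U._ConcatCropSkip()
        up = rng.standard_normal((6, 6, 6, 2)).astype(np.float32)
        skip = rng.standard_normal((10, 10, 10, 3)).astype(np.float32)
        y = cat.forward(up, skip)
        dy = np.random.default_rng(1).standard_normal(y.shape).astype(np.float32)
        dup, dskip = cat.backward(dy)
        d1 = np.random.default_rng(2).standard_normal(up.shape).astype(np.float32)
        d2 = np.random.default_rng(3).standard_normal(skip.shape).astype(np.float32)
        eps = 1e-3
        lp = float((cat.forward(up + eps * d1, skip + eps * d2) * dy).sum())
        lm = float((cat.forward(up - eps * d1, skip - eps * d2) * dy).sum())
        num = (lp - lm) / (2 * eps)
        ana = float((dup * d1).sum() + (dskip * d2).sum())
        assert num == pytest.approx(ana, rel=5e-3, abs=2e-3)


def test_loss_gradients_are_signs(rng):
    voxel = rng.normal(50, 10, size=(2, 12, 12, 12))
    aux = rng.normal(50, 10, size=(2, 2))
    ages = np.array([40.0, 60.0])
    dv, da = loss_gradients((voxel, aux), ages, LossConfig(alpha_1=0.5, alpha_2=2.0), 0)
    np.testing.assert_array_equal(dv, np.sign(voxel - ages[:, None, None, None]))
    np.testing.assert_allclose(
        da, np.array([0.5, 2.0]) * np.sign(aux - ages[:, None])
    )


def test_checkpoint_roundtrip(tmp_path, net):
    path = tmp_path / "ckpt.npz"
    save_checkpoint(net, path)
    back = load_checkpoint(path)
    assert back.spec == net.spec
    x = np.random.default_rng(3).random((52, 52, 52, 2), dtype=np.float32)
    v1, a1 = net.forward(x)
    v2, a2 = back.forward(x)
    np.testing.assert_array_equal(v1, v2)
    np.testing.assert_array_equal(a1, a2)
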