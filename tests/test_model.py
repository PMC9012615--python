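"""Architecture contracts: published layer shape traces, attention
normalisation, residual identity behaviour and ablation variants."""

import numpy as np
import pytest

from raecg.model import ABlock, RACNN, RAUNet, RBlock
from raecg.nn import Tensor


class TestRBlock:
    def test_identity_configuration_preserves_shape(self):
        rb = RBlock(16, 4, 16, (1, 1, 1), rng=np.random.default_rng(0))
        out = rb(Tensor(np.random.default_rng(1).random((2, 16, 56, 56),
                                                        dtype=np.float32)))
        assert out.shape == (2, 16, 56, 56)
        assert rb.identity

    def test_strided_configuration_halves_and_projects(self):
        rb = RBlock(16, 8, 32, (1, 2, 1), rng=np.random.default_rng(0))
        out = rb(Tensor(np.zeros((2, 16, 56, 56), dtype=np.float32)))
        assert out.shape == (2, 32, 28, 28)
        assert not rb.identity

    def test_zeroed_residual_path_reduces_to_identity(self):
        rb = RBlock(8, 4, 8, (1, 1, 1), rng=np.random.default_rng(0))
        rb.eval()  # running stats: mean 0, var 1 -> BN is affine identity
        for stage in (rb.f1, rb.f2, rb.f3):
            stage.conv.weight.data[:] = 0.0
            stage.conv.bias.data[:] = 0.0
        x = np.random.default_rng(2).standard_normal((3, 8, 10, 10)).astype(np.float32)
        assert np.allclose(rb(Tensor(x)).data, x, atol=1e-6)

    def test_channel_mismatch_raises(self):
        rb = RBlock(16, 4, 16)
        with pytest.raises(ValueError, match="channels"):
            rb(Tensor(np.zeros((1, 8, 10, 10), dtype=np.float32)))


class TestABlock:
    @pytest.mark.parametrize("c,h,w,n", [(16, 28, 28, 2), (16, 7, 7, 4),
                                         (8, 5, 9, 1), (32, 4, 4, 8)])
    def test_preserves_shape_for_valid_configs(self, c, h, w, n):
        x = np.random.default_rng(c).standard_normal((2, c, h, w)).astype(np.float32)
        out = ABlock(c, n)(Tensor(x))
        assert out.shape == (2, c, h, w)

    def test_channel_attention_weights_sum_to_one_per_group(self):
        ab = ABlock(16, 2)
        x = Tensor(np.random.default_rng(0).standard_normal((3, 16, 6, 6))
                   .astype(np.float32))
        for i in range(ab.groups):
            g0 = i * 2 * ab.half
            w = ab.channel_weights(x[:, g0 : g0 + ab.half], i)
            assert np.allclose(w.data.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_attention_weights_sum_to_one_per_channel(self):
        ab = ABlock(16, 2)
        x = Tensor(np.random.default_rng(1).standard_normal((3, 16, 6, 6))
                   .astype(np.float32))
        for i in range(ab.groups):
            g0 = i * 2 * ab.half
            w = ab.spatial_weights(x[:, g0 + ab.half : g0 + 2 * ab.half], i)
            assert np.allclose(w.data.sum(axis=(2, 3)), 1.0, atol=1e-6)

    def test_zero_affine_params_give_uniform_attention(self):
        """With W=b=0 every channel weight is 2n/C and every spatial weight
        1/(H*W); verified against a direct hand computation on a tiny map."""
        ab = ABlock(4, 1)
        ab.W1.data[:] = 0
        ab.b1.data[:] = 0
        ab.W2.data[:] = 0
        ab.b2.data[:] = 0
        x = np.random.default_rng(3).standard_normal((1, 4, 2, 2)).astype(np.float32)
        out = ab(Tensor(x)).data
        expect = x.copy()
        expect[:, :2] *= 1.5  # channel half: w = 1/2 each -> (1 + 1/2) x
        expect[:, 2:] *= 1.25  # spatial half: w = 1/(2*2) -> (1 + 1/4) x
        assert np.allclose(out, expect, atol=1e-6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ABlock(6, 2)

    def test_single_branch_ablations_run(self):
        x = Tensor(np.random.default_rng(4).standard_normal((2, 16, 8, 8))
                   .astype(np.float32))
        only_channel = ABlock(16, 2, channel_att=True, spatial_att=False)(x)
        only_spatial = ABlock(16, 2, channel_att=False, spatial_att=True)(x)
        assert only_channel.shape == x.shape
        assert only_spatial.shape == x.shape


class TestRAUNet:
    def test_published_shape_trace_at_56(self):
        unet = RAUNet(size=56, rng=np.random.default_rng(0))
        trace = {}
        out = unet(Tensor(np.random.default_rng(1).random((1, 16, 56, 56),
                                                          dtype=np.float32)), trace)
        assert out.shape == (1, 16, 56, 56)
        assert trace["unet.enc1"] == (1, 16, 28, 28)
        assert trace["unet.enc2"] == (1, 16, 14, 14)
        assert trace["unet.enc3"] == (1, 16, 7, 7)  # innermost level
        assert trace["unet.dec1"] == (1, 16, 14, 14)
        assert trace["unet.dec2"] == (1, 16, 28, 28)
        assert trace["unet.out"] == (1, 16, 56, 56)

    def test_wrong_input_size_rejected(self):
        unet = RAUNet(size=56)
        with pytest.raises(ValueError, match="56"):
            unet(Tensor(np.zeros((1, 16, 28, 28), dtype=np.float32)))

    def test_pool_and_upsample_skeleton_survives_full_ablation(self):
        unet = RAUNet(size=56, use_ablock=False, use_rblock=False,
                      use_skips=False, rng=np.random.default_rng(0))
        out = unet(Tensor(np.random.default_rng(2).random((1, 16, 56, 56),
                                                          dtype=np.float32)))
        assert out.shape == (1, 16, 56, 56)


class TestRACNN:
    def test_full_published_trace_for_224_input(self):
        model = RACNN(input_size=224, seed=0)
        model.eval()
        x = np.random.default_rng(0).random((1, 3, 224, 224), dtype=np.float32)
        scores, trace = model.forward(Tensor(x), return_trace=True)
        assert scores.shape == (1, 4)
        expected = {
            "stem.conv": (1, 16, 112, 112),
            "stem.pool": (1, 16, 56, 56),
            "rblock1": (1, 16, 56, 56),
            "rblock5": (1, 16, 56, 56),
            "unet.out": (1, 16, 56, 56),
            "fused": (1, 16, 56, 56),
            "rblock2": (1, 32, 28, 28),
            "rblock3": (1, 64, 14, 14),
            "rblock4": (1, 64, 7, 7),
            "gap": (1, 64),
            "fc": (1, 4),
        }
        for name, shape in expected.items():
            assert trace[name] == shape, name

    def test_forward_is_deterministic_in_eval_mode(self):
        model = RACNN(input_size=32, seed=5)
        model.eval()
        x = np.random.default_rng(1).random((2, 3, 32, 32), dtype=np.float32)
        a = model(Tensor(x)).data
        b = model(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_seeded_construction_is_reproducible(self):
        a = RACNN(input_size=32, seed=9).state_dict()
        b = RACNN(input_size=32, seed=9).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_wrong_input_shape_rejected(self):
        model = RACNN(input_size=32)
        with pytest.raises(ValueError, match="expected"):
            model(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))

    @pytest.mark.parametrize("ablation", [
        {"use_rblock": False},
        {"use_ablock": False},
        {"channel_att": False},
        {"spatial_att": False},
        {"top_skip": False},
        {"middle_layer": False},
    ])
    def test_every_ablation_variant_builds_and_runs(self, ablation):
        model = RACNN(input_size=32, seed=0, **ablation)
        model.eval()
        x = np.random.default_rng(2).random((2, 3, 32, 32), dtype=np.float32)
        assert model(Tensor(x)).shape == (2, 4)
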