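"""Bidirectional weighted fusion neck: resampling, normalised fusion,
full pyramid passes."""

import numpy as np
import pytest

from sproutnet.model import VariantConfig, PANNeck
from sproutnet.neck import BiFPN, Downsample, NormalizedFusion, resample
from sproutnet.nn import Tensor, seed_all


class TestResample:
    def test_up2_replicates(self, rng):
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        up = resample(Tensor(x), "up2").data
        assert up.shape == (1, 8, 8, 8)
        assert np.all(up[0, :, ::2, ::2] == x[0])
        assert np.all(up[0, :, 1::2, 1::2] == x[0])

    def test_constant_stays_constant(self):
        x = Tensor(np.full((1, 2, 3, 3), 4.5, np.float32))
        assert np.all(resample(x, "up2").data == 4.5)

    def test_down2_shape_roundtrip(self, rng):
        seed_all(0)
        down = Downsample(8)
        x = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        y = resample(x, "down2", down)
        assert y.shape == (1, 8, 4, 4)
        assert resample(y, "up2").shape == x.shape

    def test_down2_odd_rejected(self):
        seed_all(0)
        down = Downsample(4)
        with pytest.raises(ValueError, match="even"):
            resample(Tensor(np.zeros((1, 4, 5, 6), np.float32)), "down2", down)


class TestNormalizedFusion:
    def test_equal_weights_mean(self, rng):
        f = NormalizedFusion(2, conv=None, eps=1e-12)
        a = Tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(f([a, b]).data, (a.data + b.data) / 2,
                                   atol=1e-6)

    def test_single_input_scaling(self, rng):
        f = NormalizedFusion(1, conv=None, eps=1e-4)
        x = Tensor(np.ones((1, 2, 2, 2), np.float32))
        np.testing.assert_allclose(f([x]).data, 1.0 / (1.0 + 1e-4), atol=1e-7)

    def test_zero_weight_input_ignored(self, rng):
        f = NormalizedFusion(2, conv=None)
        f.raw_weights.data[:] = [2.0, 0.0]
        a = Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32) * 100)
        out1 = f([a, b]).data
        b2 = Tensor(np.zeros_like(b.data))
        np.testing.assert_allclose(out1, f([a, b2]).data, atol=1e-7)

    def test_negative_raw_weights_clamped(self, rng):
        f = NormalizedFusion(2, conv=None)
        f.raw_weights.data[:] = [1.0, -5.0]
        coef = f.coefficients()
        assert np.all(coef >= 0)
        assert coef.sum() < 1.0

    def test_permutation_equivariance(self, rng):
        f = NormalizedFusion(3, conv=None)
        f.raw_weights.data[:] = [0.5, 1.5, 2.5]
        xs = [Tensor(rng.normal(size=(1, 2, 2, 2)).astype(np.float32))
              for _ in range(3)]
        out = f(xs).data
        perm = [2, 0, 1]
        f.raw_weights.data[:] = f.raw_weights.data[perm]
        out_p = f([xs[i] for i in perm]).data
        np.testing.assert_allclose(out, out_p, atol=1e-7)

    def test_shape_mismatch_rejected(self):
        f = NormalizedFusion(2, conv=None)
        with pytest.raises(ValueError, match="mismatch"):
            f([Tensor(np.zeros((1, 2, 4, 4), np.float32)),
               Tensor(np.zeros((1, 2, 2, 2), np.float32))])

    def test_bad_construction_rejected(self):
        with pytest.raises(ValueError):
            NormalizedFusion(0, None)
        with pytest.raises(ValueError):
            NormalizedFusion(2, None, eps=0.0)


def _pyramid(rng, w=32, base=16, n=1):
    sizes = {"p2": base, "p3": base // 2, "p4": base // 4, "p5": base // 8}
    ch = {"p2": 8, "p3": 16, "p4": 32, "p5": 64}
    return {l: Tensor(rng.normal(size=(n, ch[l], s, s)).astype(np.float32))
            for l, s in sizes.items()}, ch


class TestBiFPN:
    def test_pass_preserves_shapes(self, rng):
        seed_all(0)
        feats, ch = _pyramid(rng)
        neck = BiFPN(ch, width=16)
        fused = neck.bifpn_pass(feats)
        for l in ("p2", "p3", "p4", "p5"):
            assert fused[l].shape[2:] == feats[l].shape[2:]
            assert fused[l].shape[1] == 16
        # a second stacked pass (laterals now at neck width) likewise
        neck2 = BiFPN({l: 16 for l in ch}, width=16)
        again = neck2.bifpn_pass(fused)
        for l in fused:
            assert again[l].shape == fused[l].shape

    def test_missing_level_rejected(self, rng):
        seed_all(0)
        feats, ch = _pyramid(rng)
        neck = BiFPN(ch, width=16)
        del feats["p4"]
        with pytest.raises(ValueError, match="p4"):
            neck.bifpn_pass(feats)

    def test_head_outputs_strides(self, rng):
        seed_all(0)
        feats, ch = _pyramid(rng, base=16)
        neck = BiFPN(ch, width=16)
        outs = neck(feats)
        assert [o.shape[2] for o in outs] == [8, 4, 2]   # strides 8/16/32

    def test_removing_p2_changes_p3_head(self, rng):
        """Zeroing the P2 feature alters the fused P3 output: the extra
        fine level genuinely feeds the finest head."""
        seed_all(0)
        feats, ch = _pyramid(rng)
        neck = BiFPN(ch, width=16)
        neck.eval()
        base = neck(feats)[0].data
        feats2 = dict(feats)
        feats2["p2"] = Tensor(np.zeros_like(feats["p2"].data))
        changed = neck(feats2)[0].data
        assert not np.allclose(base, changed)

    def test_td_weight_zeroing_cuts_td_path(self, rng):
        """Zeroing every top-down (intermediate-feature) fusion weight in
        the bottom-up sweep reduces the fused P2/P3 outputs to functions of
        the level inputs and the lower level only — perturbing the deeper
        levels must then leave them unchanged."""
        seed_all(0)
        feats, ch = _pyramid(rng)
        neck = BiFPN(ch, width=16)
        neck.eval()
        neck.out2.raw_weights.data[:] = [1.0, 0.0]         # (in2, up(td3))
        neck.out3.raw_weights.data[:] = [1.0, 0.0, 1.0]    # (in3, td3, down)
        base = neck.bifpn_pass(feats)
        feats2 = dict(feats)
        feats2["p4"] = Tensor(feats["p4"].data + 10.0)
        feats2["p5"] = Tensor(feats["p5"].data - 5.0)
        pert = neck.bifpn_pass(feats2)
        np.testing.assert_allclose(base["p2"].data, pert["p2"].data, atol=1e-5)
        np.testing.assert_allclose(base["p3"].data, pert["p3"].data, atol=1e-5)
        assert not np.allclose(base["p4"].data, pert["p4"].data)

    def test_constant_pyramid_propagates_constants(self):
        """With identity post-convs, all-equal weights and a constant-valued
        pyramid, each fusion emits the constant scaled by Σw/(Σw+β) —
        checked against a closed-form propagation of those factors."""
        seed_all(0)
        ch = {"p2": 4, "p3": 4, "p4": 4, "p5": 4}
        neck = BiFPN(ch, width=4, eps=1e-4)
        # make every learned stage an identity map and kill laterals' effect
        for name in ("td4", "td3", "out2", "out3", "out4", "out5"):
            getattr(neck, name).conv = None
        for l in ch:
            neck.lateral[l].conv.weight.data[...] = 0.0
            eye = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
            neck.lateral[l].conv.weight.data += eye
            neck.lateral[l].bn.gamma.data[:] = 1.0
            neck.lateral[l].bn.beta.data[:] = 0.0
        neck.eval()

        c = 3.0

        def silu(v):
            return v / (1 + np.exp(-v))

        lat = silu(c * 1.0 / np.sqrt(1 + 1e-3))    # eval BN: mean 0 var 1
        eps = 1e-4
        f2 = lat  # identical at all levels
        td4 = (lat + lat) / (2 + eps)
        td3 = (lat + td4) / (2 + eps)
        o2 = (lat + td3) / (2 + eps)
        feats = {l: Tensor(np.full((1, 4, s, s), c, np.float32))
                 for l, s in zip(("p2", "p3", "p4", "p5"), (16, 8, 4, 2))}
        # down2 convs are learned; bypass them by checking the purely
        # upsampling-driven top-down chain instead
        fused_td3 = neck.td3([neck.lateral["p3"](feats["p3"]),
                              resample(neck.td4([neck.lateral["p4"](feats["p4"]),
                                                 resample(neck.lateral["p5"](feats["p5"]), "up2")]),
                                       "up2")])
        np.testing.assert_allclose(fused_td3.data, td3, atol=1e-5)
        fused_o2 = neck.out2([neck.lateral["p2"](feats["p2"]),
                              resample(fused_td3, "up2")])
        np.testing.assert_allclose(fused_o2.data, o2, atol=1e-5)

    def test_fewer_parameters_than_pan_neck(self):
        """At nano widths the weighted-fusion neck is substantially lighter
        than the baseline path-aggregation neck."""
        seed_all(0)
        cfg = VariantConfig.named("model0")
        pan = PANNeck(cfg)
        seed_all(0)
        bifpn = BiFPN({"p2": 32, "p3": 64, "p4": 128, "p5": 256}, width=64)
        assert bifpn.num_parameters() < pan.num_parameters()
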