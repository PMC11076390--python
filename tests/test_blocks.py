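"""Block-level contracts: scSE gating bounds, asymmetric-kernel fusion
against an independent scipy oracle, dense connectivity, ASPP symmetry."""

import numpy as np
import pytest
from scipy import signal

from asdnet import nn
from asdnet.blocks import (ASCOBlock, ASPPBridge, AsymmetricConvUnit,
                           BlockConfig, DDECBlock, SCSEGate,
                           fuse_asymmetric_kernels, receptive_field_3x3)


class TestSCSE:
    def test_zero_input_gives_zero_output(self, rng):
        gate = SCSEGate(8, rng)
        out = gate(nn.Tensor(np.zeros((2, 8, 5, 5), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_output_bounded_by_twice_input(self, rng):
        gate = SCSEGate(8, rng)
        for _ in range(10):
            x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
            out = gate(nn.Tensor(x)).data
            assert (np.abs(out) <= 2 * np.abs(x) + 1e-6).all()

    def test_output_shape_equals_input_shape(self, rng):
        gate = SCSEGate(4, rng)
        x = rng.normal(size=(3, 4, 7, 9)).astype(np.float32)
        assert gate(nn.Tensor(x)).shape == x.shape

    def test_zeroed_gates_halve_and_sum_to_identity(self, rng):
        # with all gate parameters zero both sigmoids output 0.5,
        # so Y_cSE = Y_sSE = 0.5 x and their sum reproduces x
        gate = SCSEGate(2, rng)
        for p in gate.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(1, 2, 2, 2)).astype(np.float32)
        out = gate(nn.Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_spatial_gate_alone_halves_constant_input(self, rng):
        # isolate Y_sSE by zeroing the 1x1 conv: sigmoid(0) = 0.5
        gate = SCSEGate(2, rng)
        gate.spatial.weight.data[...] = 0.0
        gate.spatial.bias.data[...] = 0.0
        x = np.full((1, 2, 2, 2), 3.0, dtype=np.float32)
        y_sse = (x * 1 / (1 + np.exp(-gate.spatial(nn.Tensor(x)).data)))
        np.testing.assert_allclose(y_sse, 0.5 * x, atol=1e-7)

    def test_channel_count_must_divide_reduction(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            SCSEGate(3, rng, reduction=2)


class TestKernelFusion:
    def test_all_zero_inputs(self):
        k, b = fuse_asymmetric_kernels(np.zeros((3, 3)), np.zeros((3, 1)),
                                       np.zeros((1, 3)))
        np.testing.assert_array_equal(k, 0)
        assert b == 0

    def test_column_kernel_lands_in_centre_column(self):
        k, _ = fuse_asymmetric_kernels(np.zeros((3, 3)),
                                       np.ones((3, 1)), np.zeros((1, 3)))
        np.testing.assert_array_equal(k[:, 1], 1)
        np.testing.assert_array_equal(k[:, [0, 2]], 0)

    def test_fused_convolution_equals_branch_sum(self, rng):
        x = rng.normal(size=(8, 8))
        k33 = rng.normal(size=(3, 3))
        k31 = rng.normal(size=(3, 1))
        k13 = rng.normal(size=(1, 3))
        b = rng.normal(size=3)
        fused, bf = fuse_asymmetric_kernels(k33, k31, k13, *b)
        branch = (signal.correlate2d(x, k33, mode="same") +
                  signal.correlate2d(x, k31, mode="same") +
                  signal.correlate2d(x, k13, mode="same") + b.sum())
        fused_resp = signal.correlate2d(x, fused, mode="same") + bf
        np.testing.assert_allclose(fused_resp, branch, atol=1e-6)

    def test_wrong_shapes_rejected(self):
        with pytest.raises(ValueError):
            fuse_asymmetric_kernels(np.zeros((3, 3)), np.zeros((1, 3)),
                                    np.zeros((1, 3)))


class TestASCO:
    def test_branch_sum_equals_fused_kernel_oracle(self, rng):
        unit = AsymmetricConvUnit(2, 3, rng)
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        got = unit.branch_sum(nn.Tensor(x)).data
        fused, bf = fuse_asymmetric_kernels(
            unit.conv33.weight.data, unit.conv31.weight.data,
            unit.conv13.weight.data, unit.conv33.bias.data,
            unit.conv31.bias.data, unit.conv13.bias.data)
        for o in range(3):
            ref = sum(signal.correlate2d(x[0, c].astype(np.float64),
                                         fused[o, c], mode="same")
                      for c in range(2)) + bf[o]
            np.testing.assert_allclose(got[0, o], ref, atol=1e-5)

    def test_zero_weights_give_constant_summed_bias(self, rng):
        unit = AsymmetricConvUnit(2, 3, rng)
        for conv in (unit.conv33, unit.conv31, unit.conv13):
            conv.weight.data[...] = 0.0
        unit.conv33.bias.data[:] = 0.5
        unit.conv31.bias.data[:] = 0.25
        unit.conv13.bias.data[:] = 0.25
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        out = unit.branch_sum(nn.Tensor(x)).data
        np.testing.assert_allclose(out, 1.0, atol=1e-6)

    def test_block_preserves_spatial_shape(self, rng):
        block = ASCOBlock(3, 8, rng)
        x = rng.normal(size=(2, 3, 10, 14)).astype(np.float32)
        assert block(nn.Tensor(x)).shape == (2, 8, 10, 14)

    def test_rejects_sub_3x3_input(self, rng):
        block = ASCOBlock(2, 4, rng)
        with pytest.raises(ValueError, match="spatial"):
            block(nn.Tensor(rng.normal(size=(1, 2, 2, 5)).astype(np.float32)))


class TestDDEC:
    def test_output_shape_contract(self, rng):
        block = DDECBlock(6, 8, rng)
        x = rng.normal(size=(2, 6, 9, 11)).astype(np.float32)
        assert block(nn.Tensor(x)).shape == (2, 8, 9, 11)

    def test_dense_connectivity_dependency_probe(self, rng):
        # perturbing layer 1's convolution must change the input of every
        # later dense layer (captured via forward hooks on the conv inputs)
        block = DDECBlock(4, 8, rng).eval()
        x = nn.Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))

        def capture():
            seen = []
            feats = x
            with nn.no_grad():
                for bn, conv in block.dense_layers:
                    inp = nn.relu(bn(feats))
                    seen.append(inp.data.copy())
                    out = conv(inp)
                    feats = nn.concat([feats, out], axis=1)
            return seen

        base = capture()
        block.conv0.weight.data += 0.5
        perturbed = capture()
        for i in range(1, len(base)):
            assert not np.allclose(base[i], perturbed[i])

    def test_final_layer_uses_dilated_kernel(self, rng):
        cfg = BlockConfig(ddec_dilation=2)
        block = DDECBlock(4, 8, rng, cfg)
        *_, (bn, conv) = block.dense_layers
        assert conv.dilation == 2
        assert receptive_field_3x3(conv.dilation) == 5
        for _, earlier in block.dense_layers[:-1]:
            assert earlier.dilation == 1


class TestASPP:
    def test_shape_preserved(self, rng):
        aspp = ASPPBridge(8, 8, rng)
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        assert aspp(nn.Tensor(x)).shape == (2, 8, 4, 4)

    def test_constant_input_gives_constant_output(self, rng):
        aspp = ASPPBridge(4, 4, rng).eval()
        x = np.full((1, 4, 6, 6), 0.7, dtype=np.float32)
        with nn.no_grad():
            out = aspp(nn.Tensor(x)).data
        for c in range(4):
            assert np.ptp(out[0, c]) < 1e-5

    def test_branch_receptive_fields(self):
        assert [receptive_field_3x3(r) for r in (6, 12, 18)] == [13, 25, 37]

    def test_determinism_at_inference(self, rng):
        aspp = ASPPBridge(4, 4, rng).eval()
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        with nn.no_grad():
            a = aspp(nn.Tensor(x)).data
            b = aspp(nn.Tensor(x)).data
        np.testing.assert_array_equal(a, b)
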