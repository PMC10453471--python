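"""Network blocks: shape contracts, attention bounds, receptive fields,
and parameter counts against closed-form / enumeration oracles."""

import numpy as np
import pytest

from spineseg import nn
from spineseg.blocks import (ASPP, CHASPP, AttentionGate, BottleneckSpec,
                             InvertedResidual, ResidualBlock,
                             enumerate_parameters)
from spineseg.nn import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def _make_positive(module):
    """Force positive conv weights / zero biases so relu acts as identity on
    impulse inputs and support equals the receptive field."""
    for _, p in module.named_parameters():
        if p.data.ndim >= 2:
            p.data = np.abs(p.data) + 0.01
        else:
            p.data[...] = 0.0


def impulse_support(module, size=31):
    """Nonzero output support of a centred impulse (linearised module)."""
    _make_positive(module)
    x = np.zeros((1, module_in_channels(module), size, size), np.float32)
    x[:, :, size // 2, size // 2] = 1.0
    with nn.no_grad():
        y = module(Tensor(x)).data[0].sum(axis=0)
    ys, xs = np.nonzero(y > 1e-12)
    return np.ptp(ys) + 1, np.ptp(xs) + 1, int((y > 1e-12).sum())


def module_in_channels(module):
    return module._in_channels


class TestResidualBlock:
    def test_zero_conv_path_passes_input_through(self, rng):
        blk = ResidualBlock(4, 4, rng, norm=False)
        for seq in (blk.path1, blk.path2):
            seq.layers[0].weight.data[...] = 0.0
            seq.layers[0].bias.data[...] = 0.0
        x = np.abs(rng.normal(size=(1, 4, 8, 8))).astype(np.float32)
        out = blk(Tensor(x))
        np.testing.assert_allclose(out.data, x, rtol=1e-6)

    def test_output_channels_and_extents(self, rng):
        blk = ResidualBlock(8, 16, rng)
        out = blk(Tensor(rng.normal(size=(1, 8, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 16, 32, 32)

    @pytest.mark.parametrize("C", [4, 8])
    def test_parameter_count_closed_form(self, C, rng):
        """Identity-shortcut block, biased convs, no norm: 2*(9C^2 + C)."""
        blk = ResidualBlock(C, C, rng, norm=False)
        total = sum(int(np.prod(s)) for _, s in enumerate_parameters(blk))
        assert total == 2 * (9 * C * C + C)
        assert blk.count_parameters() == total


class TestAttentionGate:
    def test_zero_values_annihilate_output(self, rng):
        gate = AttentionGate(4, 8, rng)
        gate.to_v.weight.data[...] = 0.0
        gate.to_v.bias.data[...] = 0.0
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(gate(skip, g).data, 0.0)

    def test_zero_scores_give_half_of_values(self, rng):
        gate = AttentionGate(4, 8, rng)
        gate.to_q.weight.data[...] = 0.0   # orthogonal projections: e = 0
        gate.to_q.bias.data[...] = 0.0
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        with nn.no_grad():
            out = gate(skip, g)
            v = gate.to_v(skip)
        np.testing.assert_allclose(out.data, 0.5 * v.data, rtol=1e-5)

    def test_weights_strictly_inside_unit_interval(self, rng):
        gate = AttentionGate(4, 8, rng)
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        alpha = gate.attention(skip, g).data
        assert np.all(alpha > 0.0) and np.all(alpha < 1.0)

    def test_output_bounded_by_values(self, rng):
        gate = AttentionGate(4, 8, rng)
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        with nn.no_grad():
            out = gate(skip, g).data
            v = gate.to_v(skip).data
        assert np.all(np.abs(out) <= np.abs(v) + 1e-6)

    def test_gate_upsampled_when_half_resolution(self, rng):
        gate = AttentionGate(4, 8, rng)
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        assert gate(skip, g).shape == (1, 4, 8, 8)

    def test_incompatible_extents_rejected(self, rng):
        gate = AttentionGate(4, 8, rng)
        skip = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        g = Tensor(np.zeros((1, 8, 5, 5), np.float32))
        with pytest.raises(ValueError):
            gate(skip, g)


class TestASPP:
    def test_extents_preserved_and_projection_width(self, rng):
        aspp = ASPP(8, 16, rng, rates=(1, 2, 4, 8))
        x = Tensor(rng.normal(size=(1, 8, 32, 32)).astype(np.float32))
        assert aspp(x).shape == (1, 16, 32, 32)
        # concatenation arithmetic: (|rates| + 1) * branch width
        proj_conv = aspp.project.layers[0]
        assert proj_conv.weight.shape[1] == (4 + 1) * 16

    def test_rate3_branch_receptive_field_is_seven(self, rng):
        aspp = ASPP(1, 2, rng, rates=(3,), norm=False)
        aspp._in_channels = 1
        h, w, _ = impulse_support(aspp)
        assert (h, w) == (7, 7)

    def test_empty_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            ASPP(4, 4, rng, rates=())


class TestCHASPP:
    def test_extents_preserved(self, rng):
        ch = CHASPP(8, 16, rng)
        x = Tensor(rng.normal(size=(1, 8, 24, 24)).astype(np.float32))
        assert ch(x).shape == (1, 16, 24, 24)

    def test_composed_receptive_field_root2_branch3(self, rng):
        """Root rate 2 (RF 5) into branch rate 3 (RF 7): composed RF 11."""
        ch = CHASPP(1, 2, rng, root_rate=2, branch_rates=(3,), norm=False)
        ch._in_channels = 1
        h, w, _ = impulse_support(ch)
        assert (h, w) == (11, 11)

    def test_composition_samples_more_taps_than_single_dilated_conv(self, rng):
        """The root+branch cascade touches more distinct input offsets than
        the 9 taps of one 3x3 dilated conv with the same receptive field."""
        ch = CHASPP(1, 2, rng, root_rate=2, branch_rates=(3,), norm=False)
        ch._in_channels = 1
        _, _, n_taps = impulse_support(ch)
        assert n_taps > 9

    def test_invalid_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            CHASPP(4, 4, rng, root_rate=0)


class TestInvertedResidual:
    def test_standard_stack_row_16_to_24(self, rng):
        """The stride-2 expansion-6 stage maps 112^2 x 16 -> 56^2 x 24."""
        stage = InvertedResidual(16, BottleneckSpec(t=6, c=24, n=2, a=2), rng)
        x = Tensor(rng.normal(size=(1, 16, 112, 112)).astype(np.float32))
        with nn.no_grad():
            assert stage(x).shape == (1, 24, 56, 56)

    def test_expansion_width(self, rng):
        stage = InvertedResidual(16, BottleneckSpec(t=6, c=24, n=1, a=1), rng)
        expand_conv = stage.units[0].expand.layers[0]
        assert expand_conv.weight.shape[0] == 96  # 16 * 6 hidden channels

    def test_depthwise_parameter_count(self, rng):
        """Biased depthwise 3x3 over 8 channels: 9*8 + 8 = 80 parameters."""
        conv = nn.Conv2d(8, 8, 3, rng, groups=8, bias=True)
        assert conv.weight.data.size + conv.bias.data.size == 80

    def test_shortcut_only_when_geometry_permits(self, rng):
        with_sc = InvertedResidual(24, BottleneckSpec(t=6, c=24, n=1, a=1),
                                   rng)
        without = InvertedResidual(16, BottleneckSpec(t=6, c=24, n=1, a=2),
                                   rng)
        assert with_sc.units[0].use_shortcut
        assert not without.units[0].use_shortcut

    def test_stride_only_in_first_repeat(self, rng):
        stage = InvertedResidual(16, BottleneckSpec(t=6, c=24, n=3, a=2), rng)
        strides = [u.depthwise.layers[0].stride for u in stage.units]
        assert strides == [2, 1, 1]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BottleneckSpec(t=0, c=8)
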