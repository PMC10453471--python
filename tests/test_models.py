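"""Both networks: structure, shape contracts, probability normalization,
determinism, parameter budgets, and the multi-view fusion geometry."""

import numpy as np
import pytest

from spineseg import nn
from spineseg.blocks import CHASPP, AttentionGate
from spineseg.chaspprau import (CHASPPRAUNet, SegModelConfig, build_seg_model,
                                count_parameters, segment_slice,
                                segment_volume)
from spineseg.mru3d import (MRUNet3D, RecogModelConfig, build_recog_model,
                            encode_view, fuse_views, recognize)
from spineseg.nifti_io import LabelMap, Volume, default_affine
from spineseg.nn import Tensor

SMALL_SEG = SegModelConfig(base_width=4, depth=2, seed=0)
SMALL_RECOG = RecogModelConfig(fused_channels=8, decoder_widths=(8, 8, 4, 4),
                               out_classes=5, seed=0)


@pytest.fixture(scope="module")
def seg_model():
    return build_seg_model(SMALL_SEG).eval()


@pytest.fixture(scope="module")
def recog_model():
    return build_recog_model(SMALL_RECOG).eval()


class TestSegModelStructure:
    def test_depth3_has_three_chaspp_and_three_gates(self):
        model = build_seg_model(SegModelConfig(base_width=4, depth=3))
        n_chaspp = sum(isinstance(m, CHASPP) for m in model.modules())
        n_gates = sum(isinstance(m, AttentionGate) for m in model.modules())
        assert n_chaspp == 3
        assert n_gates == 3

    def test_default_config_shape_contract(self):
        model = build_seg_model(SegModelConfig()).eval()
        probs = segment_slice(model, np.zeros((256, 256), np.float32))
        assert probs.shape == (2, 256, 256)

    def test_residual_block_ablation_toggle(self):
        from spineseg.blocks import ResidualBlock
        on = build_seg_model(SegModelConfig(base_width=4, depth=2,
                                            residual_blocks=True))
        off = build_seg_model(SegModelConfig(base_width=4, depth=2,
                                             residual_blocks=False))
        assert any(isinstance(m, ResidualBlock) for m in on.modules())
        assert not any(isinstance(m, ResidualBlock) for m in off.modules())

    def test_parameter_count_equals_enumeration(self, seg_model):
        from spineseg.blocks import enumerate_parameters
        total = sum(int(np.prod(s))
                    for _, s in enumerate_parameters(seg_model))
        assert count_parameters(seg_model) == total

    def test_count_invariant_to_mode(self, seg_model):
        n_eval = count_parameters(seg_model)
        seg_model.train()
        n_train = count_parameters(seg_model)
        seg_model.eval()
        assert n_eval == n_train

    def test_frozen_parameters_excluded(self):
        model = build_seg_model(SMALL_SEG)
        full = count_parameters(model)
        head_size = model.head.weight.data.size + model.head.bias.data.size
        model.head.weight.requires_grad = False
        model.head.bias.requires_grad = False
        assert count_parameters(model) == full - head_size


class TestSegmentSlice:
    def test_probabilities_sum_to_one(self, seg_model, rng):
        probs = segment_slice(seg_model,
                              rng.normal(size=(64, 64)).astype(np.float32))
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_deterministic_in_eval_mode(self, seg_model, rng):
        s = rng.normal(size=(64, 64)).astype(np.float32)
        np.testing.assert_array_equal(segment_slice(seg_model, s),
                                      segment_slice(seg_model, s))

    def test_wrong_rank_rejected(self, seg_model):
        with pytest.raises(ValueError):
            segment_slice(seg_model, np.zeros((4, 64, 64), np.float32))


class TestSegmentVolume:
    def test_shape_and_binary_labels(self, seg_model, rng):
        v = Volume(rng.normal(size=(16, 32, 32)), default_affine())
        out = segment_volume(seg_model, v, plane="sagittal")
        assert out.shape == v.shape
        assert set(np.unique(out.data)) <= {0, 1}

    def test_argmax_ties_resolve_to_background(self, rng):
        model = build_seg_model(SMALL_SEG).eval()
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0  # all-equal logits at every pixel
        v = Volume(rng.normal(size=(8, 16, 16)), default_affine())
        out = segment_volume(model, v)
        np.testing.assert_array_equal(out.data, 0)

    def test_invalid_plane_rejected(self, seg_model, rng):
        v = Volume(rng.normal(size=(8, 16, 16)), default_affine())
        with pytest.raises(ValueError):
            segment_volume(seg_model, v, plane="oblique")


class TestRecogStructure:
    def test_three_encoders_share_no_parameters(self, recog_model):
        ids_by_view = [
            {id(p) for p in enc.parameters()}
            for enc in (recog_model.enc_axial, recog_model.enc_sagittal,
                        recog_model.enc_coronal)]
        assert not (ids_by_view[0] & ids_by_view[1])
        assert not (ids_by_view[0] & ids_by_view[2])
        assert not (ids_by_view[1] & ids_by_view[2])
        n_each = [sum(p.data.size for p in enc.parameters())
                  for enc in (recog_model.enc_axial,
                              recog_model.enc_sagittal,
                              recog_model.enc_coronal)]
        assert n_each[0] == n_each[1] == n_each[2]

    def test_parameter_count_equals_enumeration(self, recog_model):
        from spineseg.blocks import enumerate_parameters
        total = sum(int(np.prod(s))
                    for _, s in enumerate_parameters(recog_model))
        assert recog_model.count_parameters() == total

    def test_forward_shape_contract(self, recog_model, rng):
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32)
        with nn.no_grad():
            logits = recog_model(x)
        assert logits.shape == (1, 5, 16, 16, 16)

    def test_indivisible_grid_rejected(self, recog_model):
        with pytest.raises(ValueError):
            recog_model(np.zeros((2, 12, 12, 12), np.float32))


class TestEncodeViewAndFusion:
    def test_encode_view_fusion_grid_arithmetic(self, recog_model, rng):
        """64^3 input at downsample 8 -> (1, fused_channels, 8, 8, 8)."""
        v = rng.normal(size=(64, 64, 64)).astype(np.float32)
        f = encode_view(recog_model, v, "axial")
        assert f.shape == (1, SMALL_RECOG.fused_channels, 8, 8, 8)

    def test_three_views_have_identical_extents(self, recog_model, rng):
        v = rng.normal(size=(16, 24, 32)).astype(np.float32)
        feats = [encode_view(recog_model, v, a)
                 for a in ("axial", "sagittal", "coronal")]
        assert feats[0].shape == feats[1].shape == feats[2].shape

    def test_axis_permutation_symmetry(self, rng):
        """Permuting the volume axes and the view argument consistently
        gives the same features up to that permutation."""
        cfg = RecogModelConfig(fused_channels=4, out_classes=3, seed=1)
        model = build_recog_model(cfg).eval()
        v = rng.normal(size=(16, 16, 16)).astype(np.float32)
        f_ax = encode_view(model, v, "axial").data          # slices along z
        # cycle the axes so the sagittal slicing axis traverses what was z
        # and every slice carries the same (H, W) = (y, x) content
        v_cycled = v.transpose(1, 2, 0)
        model.enc_sagittal = model.enc_axial  # same weights for both views
        f_sag = encode_view(model, v_cycled, "sagittal").data
        np.testing.assert_allclose(f_ax, f_sag.transpose(0, 1, 4, 2, 3),
                                   atol=1e-5)

    def test_fuse_views_concatenation_order_and_blocks(self):
        shape = (1, 4, 2, 2, 2)
        fa = Tensor(np.full(shape, 1.0, np.float32))
        fs = Tensor(np.full(shape, 2.0, np.float32))
        fc = Tensor(np.full(shape, 3.0, np.float32))
        fused = fuse_views(fa, fs, fc)
        assert fused.shape == (1, 12, 2, 2, 2)
        np.testing.assert_array_equal(fused.data[0, :4], 1.0)
        np.testing.assert_array_equal(fused.data[0, 4:8], 2.0)
        np.testing.assert_array_equal(fused.data[0, 8:], 3.0)

    def test_mismatched_extents_rejected(self):
        fa = Tensor(np.zeros((1, 4, 2, 2, 2), np.float32))
        fb = Tensor(np.zeros((1, 4, 4, 2, 2), np.float32))
        with pytest.raises(ValueError):
            fuse_views(fa, fb, fa)


class TestRecognize:
    def test_output_shape_and_label_range(self, recog_model, rng):
        v = Volume(rng.normal(size=(16, 16, 16)), default_affine())
        mask = LabelMap(np.ones(v.shape, np.int16), v.affine)
        out = recognize(recog_model, v, mask)
        assert out.shape == v.shape
        assert out.data.min() >= 0
        assert out.data.max() < SMALL_RECOG.out_classes

    def test_probabilities_sum_to_one(self, recog_model, rng):
        x = rng.normal(size=(2, 16, 16, 16)).astype(np.float32)
        with nn.no_grad():
            probs = nn.softmax(recog_model(x), axis=1)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-5)

    def test_labels_zeroed_outside_stage1_mask(self, recog_model, rng):
        v = Volume(rng.normal(size=(16, 16, 16)), default_affine())
        mask_data = np.zeros(v.shape, np.int16)
        mask_data[4:12, 4:12, 4:12] = 1
        out = recognize(recog_model, v, LabelMap(mask_data, v.affine))
        assert np.all(out.data[mask_data == 0] == 0)

    def test_misaligned_mask_rejected(self, recog_model, rng):
        v = Volume(rng.normal(size=(16, 16, 16)), default_affine())
        mask = LabelMap(np.ones((8, 16, 16), np.int16), default_affine())
        with pytest.raises(ValueError):
            recognize(recog_model, v, mask)


class TestParameterBudget:
    """Reference configurations stay under the published comparator counts."""

    def test_stage1_under_unet_comparator(self):
        assert build_seg_model(SegModelConfig()).count_parameters() < 1_941_105

    def test_stage2_under_3d_unet_comparator(self):
        n = build_recog_model(RecogModelConfig()).count_parameters()
        assert n < 19_069_955

    def test_combined_under_published_total(self):
        total = (build_seg_model(SegModelConfig()).count_parameters()
                 + build_recog_model(RecogModelConfig()).count_parameters())
        assert total < 1_245_155
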