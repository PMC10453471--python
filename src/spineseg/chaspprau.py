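"""Stage 1: 2D residual-attention U-Net with cascaded hierarchical ASPP
(CHASPP) modules for binary spine segmentation, applied slice-wise.

Encoder (per level): residual block -> 2x2 max-pool -> CHASPP.  A residual
block forms the bottleneck.  Decoder (per level): nearest upsample x2 ->
attention gate (skip from that level's residual block, gated by the decoder
state) -> channel concatenation -> residual block.  A final 1x1 convolution
maps to the two classes (background / spine).  Dropout acts in the
bottleneck and decoder blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import CHASPP, AttentionGate, ConvBlock2d, ResidualBlock
from .nifti_io import LabelMap, Volume
from .nn import Tensor

PLANES = ("axial", "sagittal", "coronal")
#: canonical (z, y, x) array axis sliced by each anatomical plane
PLANE_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass
class SegModelConfig:
    base_width: int = 16
    depth: int = 3
    chaspp_root_rate: int = 2
    chaspp_branch_rates: tuple[int, int, int] = (1, 2, 3)
    dropout: float = 0.3
    in_channels: int = 1
    out_classes: int = 2
    residual_blocks: bool = True   # ablation toggle: False -> plain conv blocks
    norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class CHASPPRAUNet(nn.Module):
    """The stage-1 segmentation network."""

    def __init__(self, cfg: SegModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(cfg.seed + 1)
        Block = ResidualBlock if cfg.residual_blocks else ConvBlock2d
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth + 1)]

        self.enc_blocks, self.chaspps = [], []
        cin = cfg.in_channels
        for lvl in range(cfg.depth):
            self.enc_blocks.append(Block(cin, widths[lvl], rng, cfg.norm))
            self.chaspps.append(CHASPP(
                widths[lvl], widths[lvl + 1], rng,
                root_rate=cfg.chaspp_root_rate,
                branch_rates=cfg.chaspp_branch_rates,
                branch_width=widths[lvl], norm=cfg.norm))
            cin = widths[lvl + 1]
        self.bottleneck = Block(widths[cfg.depth], widths[cfg.depth], rng,
                                cfg.norm)
        self.gates, self.dec_blocks = [], []
        for lvl in reversed(range(cfg.depth)):
            self.gates.append(AttentionGate(widths[lvl], widths[lvl + 1], rng))
            self.dec_blocks.append(Block(widths[lvl + 1] + widths[lvl],
                                         widths[lvl], rng, cfg.norm))
        self.head = nn.Conv2d(widths[0], cfg.out_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Raw logits, shape (N, out_classes, H, W)."""
        cfg = self.cfg
        skips = []
        for block, chaspp in zip(self.enc_blocks, self.chaspps):
            x = block(x)
            skips.append(x)
            x = nn.maxpool2d(x)
            x = chaspp(x)
        x = self.bottleneck(x)
        if self.training and cfg.dropout > 0:
            x = nn.dropout(x, cfg.dropout, self.drop_rng)
        for gate, block, skip in zip(self.gates, self.dec_blocks,
                                     reversed(skips)):
            x = nn.upsample2d(x, 2)
            att = gate(skip, x)
            x = block(nn.concat([x, att], axis=1))
            if self.training and cfg.dropout > 0:
                x = nn.dropout(x, cfg.dropout, self.drop_rng)
        return self.head(x)


def build_seg_model(cfg: SegModelConfig | None = None) -> CHASPPRAUNet:
    return CHASPPRAUNet(cfg or SegModelConfig())


def segment_slice(model: CHASPPRAUNet, s: np.ndarray) -> np.ndarray:
    """Per-class probability map for one 2D slice, channels-first (C, H, W)."""
    s = np.asarray(s, dtype=np.float32)
    if s.ndim != 2:
        raise ValueError(f"expected a 2D slice, got rank {s.ndim}")
    with nn.no_grad():
        logits = model(Tensor(s[None, None]))
        probs = nn.softmax(logits, axis=1)
    return probs.data[0]


def segment_batch(model: CHASPPRAUNet, slices: np.ndarray) -> np.ndarray:
    """Probabilities for a (N, H, W) stack of slices -> (N, C, H, W)."""
    with nn.no_grad():
        logits = model(Tensor(np.asarray(slices, np.float32)[:, None]))
        return nn.softmax(logits, axis=1).data


def segment_volume(model: CHASPPRAUNet, v: Volume,
                   plane: str = "sagittal", batch: int = 8) -> LabelMap:
    """Slice the volume in `plane`, segment each slice, arg-max, restack.

    Arg-max ties resolve to the lower class index (background wins ties).
    """
    if plane not in PLANE_AXIS:
        raise ValueError(f"plane must be one of {PLANES}")
    axis = PLANE_AXIS[plane]
    data = np.moveaxis(v.data.astype(np.float32), axis, 0)
    out = np.empty(data.shape, dtype=np.int16)
    for start in range(0, data.shape[0], batch):
        probs = segment_batch(model, data[start:start + batch])
        out[start:start + batch] = probs.argmax(axis=1).astype(np.int16)
    return LabelMap(np.ascontiguousarray(np.moveaxis(out, 0, axis)), v.affine)


def count_parameters(model: nn.Module) -> int:
    """Trainable scalars; invariant to train/eval mode, frozen excluded."""
    return model.count_parameters()
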