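"""Stage 2: 3D multi-view mobile residual U-Net for per-vertebra recognition.

Three independent lightweight 2D encoders (width-reduced inverted-residual
stacks with residual blocks interleaved) process every axial, sagittal and
coronal slice of the input.  Per-slice feature maps are restacked along the
slicing axis and linearly resampled to a common fusion grid at 1/8, 1/4 and
1/2 of the input resolution; the three views are concatenated channel-wise
(axial, sagittal, coronal order) at each scale.  A 3D decoder upsamples from
the 1/8-scale fusion in three x2 steps, consuming the 1/4 and 1/2 fusions as
skips, and ends in a 1x1x1 convolution over the classes.

The network input is a two-channel stack of the normalized CT and the
stage-1 binary spine mask; the predicted label volume is zeroed outside that
mask, which enforces the two-stage cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import BottleneckSpec, InvertedResidual, ResidualBlock
from .chaspprau import PLANE_AXIS, PLANES
from .nifti_io import LabelMap, Volume
from .nn import Tensor

#: reduced-width bottleneck stack (a ~0.35 width multiple of the standard
#: stack, truncated after the stride-8 stage)
DEFAULT_STAGES = (
    BottleneckSpec(t=1, c=8, n=1, a=1),
    BottleneckSpec(t=6, c=12, n=2, a=2),
    BottleneckSpec(t=6, c=16, n=3, a=2),
)


@dataclass
class RecogModelConfig:
    stem_width: int = 12
    stages: tuple[BottleneckSpec, ...] = DEFAULT_STAGES
    encoder_downsample: int = 8
    fused_channels: int = 32        # per view at the 1/8 fusion
    skip_channels: tuple[int, int] = (8, 8)   # per view at 1/4 and 1/2
    decoder_widths: tuple[int, int, int, int] = (32, 16, 8, 8)
    dropout: float = 0.3
    out_classes: int = 25           # background + C1..L5 + an L6 allowance
    input_channels: int = 2         # CT + stage-1 mask
    residual_blocks: bool = True
    norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        d = self.encoder_downsample
        if d < 2 or d & (d - 1):
            raise ValueError("encoder_downsample must be a power of 2")


class ConvBlock3d(nn.Module):
    """3x3x3 conv -> [BN] -> ReLU."""

    def __init__(self, cin: int, cout: int, rng, norm: bool = True):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 3, rng, bias=not norm)
        self.bn = nn.BatchNorm(cout) if norm else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn(self.conv(x)))


class ViewEncoder(nn.Module):
    """2D encoder for one view; exposes features at strides 2, 4 and 8."""

    def __init__(self, cfg: RecogModelConfig, rng):
        super().__init__()
        self.stem = nn.Conv2d(cfg.input_channels, cfg.stem_width, 3, rng,
                              stride=2, bias=not cfg.norm)
        self.stem_bn = nn.BatchNorm(cfg.stem_width) if cfg.norm else nn.Identity()
        self.stages, self.res = [], []
        cin = cfg.stem_width
        stride = 2
        self._tap_stage = {}
        for i, spec in enumerate(cfg.stages):
            self.stages.append(InvertedResidual(cin, spec, rng, cfg.norm))
            if cfg.residual_blocks:
                self.res.append(ResidualBlock(spec.c, spec.c, rng, cfg.norm))
            else:
                self.res.append(nn.Identity())
            cin = spec.c
            stride *= spec.a
            self._tap_stage[stride] = i
        c4, c2 = cfg.skip_channels
        self.proj2 = nn.Conv2d(self._channels_at(2), c2, 1, rng)
        self.proj4 = nn.Conv2d(self._channels_at(4), c4, 1, rng)
        self.proj8 = nn.Conv2d(self._channels_at(8), cfg.fused_channels, 1, rng)

    def _channels_at(self, stride: int) -> int:
        if stride == 2 and 2 not in self._tap_stage:
            return self.stem.weight.shape[0]
        return self.stages[self._tap_stage[stride]].out_channels

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = nn.relu(self.stem_bn(self.stem(x)))
        taps = {2: x}
        stride = 2
        for stage, res in zip(self.stages, self.res):
            x = stage(x)
            x = res(x)
            stride *= [u.depthwise.layers[0].stride
                       for u in stage.units][0]
            taps[stride] = x
        return (self.proj2(taps[2]), self.proj4(taps[4]), self.proj8(taps[8]))


def _encode_axis(encoder: ViewEncoder, x: np.ndarray, axis_name: str,
                 grid: tuple[int, int, int]) -> list[Tensor]:
    """Run one view's encoder over every slice along its axis and restack.

    x: (C, z, y, x) input array.  Returns feature volumes (1, c, z/s, y/s,
    x/s) for s in (2, 4, 8), linearly resampled along the slicing axis.
    """
    axis = PLANE_AXIS[axis_name]  # 0=z (axial), 1=y (coronal), 2=x (sagittal)
    sp = 1 + axis
    # slices along `sp` become the batch; remaining two axes are (H, W)
    perm = [sp, 0] + [i for i in (1, 2, 3) if i != sp]
    batch = Tensor(np.ascontiguousarray(np.transpose(x, perm)))
    feats = encoder(batch)
    out = []
    rest = [i for i in (1, 2, 3) if i != sp]
    for s, f in zip((2, 4, 8), feats):
        # f is (slice_axis, c, rest0, rest1); back to (1, c, z', y', x')
        order = [1] + [0 if i == sp else (2 if i == rest[0] else 3)
                       for i in (1, 2, 3)]
        f = f.transpose(tuple(order))
        f = nn.axis_resample(f, axis + 1, grid[axis] // s)
        out.append(f.reshape((1,) + f.shape))
    return out


def fuse_views(f_ax: Tensor, f_sag: Tensor, f_cor: Tensor) -> Tensor:
    """Channel-wise concatenation in fixed (axial, sagittal, coronal) order."""
    for other in (f_sag, f_cor):
        if other.shape[2:] != f_ax.shape[2:] or other.shape[1] != f_ax.shape[1]:
            raise ValueError(
                f"view feature extents differ: {f_ax.shape} vs {other.shape}")
    return nn.concat([f_ax, f_sag, f_cor], axis=1)


class MRUNet3D(nn.Module):
    """The stage-2 recognition network."""

    def __init__(self, cfg: RecogModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(cfg.seed + 1)
        self.enc_axial = ViewEncoder(cfg, rng)
        self.enc_sagittal = ViewEncoder(cfg, rng)
        self.enc_coronal = ViewEncoder(cfg, rng)
        c4, c2 = cfg.skip_channels
        w8, w4, w2, w1 = cfg.decoder_widths
        self.dec8 = ConvBlock3d(3 * cfg.fused_channels, w8, rng, cfg.norm)
        self.dec4 = ConvBlock3d(w8 + 3 * c4, w4, rng, cfg.norm)
        self.dec2 = ConvBlock3d(w4 + 3 * c2, w2, rng, cfg.norm)
        self.dec1 = ConvBlock3d(w2, w1, rng, cfg.norm)
        self.head = nn.Conv3d(w1, cfg.out_classes, 1, rng)

    def encoder(self, axis_name: str) -> ViewEncoder:
        return {"axial": self.enc_axial, "sagittal": self.enc_sagittal,
                "coronal": self.enc_coronal}[axis_name]

    def _dropout(self, x: Tensor) -> Tensor:
        if self.training and self.cfg.dropout > 0:
            return nn.dropout(x, self.cfg.dropout, self.drop_rng)
        return x

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """x: (C, z, y, x) channel stack -> logits (1, classes, z, y, x)."""
        if isinstance(x, Tensor):
            x = x.data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.cfg.input_channels:
            raise ValueError(
                f"expected ({self.cfg.input_channels}, z, y, x), got {x.shape}")
        grid = x.shape[1:]
        if any(g % 8 for g in grid):
            raise ValueError(f"grid {grid} must be divisible by 8")
        pyr = {name: _encode_axis(self.encoder(name), x, name, grid)
               for name in PLANES}
        fused = [fuse_views(pyr["axial"][i], pyr["sagittal"][i],
                            pyr["coronal"][i]) for i in range(3)]
        f2, f4, f8 = fused
        h = self._dropout(self.dec8(f8))
        h = _upsample3d(h)
        h = self._dropout(self.dec4(nn.concat([h, f4], axis=1)))
        h = _upsample3d(h)
        h = self._dropout(self.dec2(nn.concat([h, f2], axis=1)))
        h = _upsample3d(h)
        h = self.dec1(h)
        return self.head(h)


def _upsample3d(x: Tensor) -> Tensor:
    """Nearest x2 upsampling of the three trailing spatial axes."""
    n, c, d, hh, w = x.shape
    x = nn.upsample2d(x, 2)                      # doubles (h, w)
    x = x.transpose((0, 1, 3, 4, 2))
    x = nn.axis_resample(x, 4, 2 * d)            # linear along depth
    return x.transpose((0, 1, 4, 2, 3))


def build_recog_model(cfg: RecogModelConfig | None = None) -> MRUNet3D:
    return MRUNet3D(cfg or RecogModelConfig())


def encode_view(model: MRUNet3D, v: Volume | np.ndarray,
                axis: str) -> Tensor:
    """Feature volume of one view at the 1/8 fusion grid."""
    if axis not in PLANE_AXIS:
        raise ValueError(f"axis must be one of {PLANES}")
    x = v.data if isinstance(v, Volume) else np.asarray(v)
    if x.ndim == 3:
        x = np.stack([x, np.zeros_like(x)])  # pad the mask channel
    x = x.astype(np.float32)
    with nn.no_grad():
        return _encode_axis(model.encoder(axis), x, axis, x.shape[1:])[2]


def recognize(model: MRUNet3D, v: Volume, spine_mask: LabelMap) -> LabelMap:
    """Multi-class vertebra labels for a preprocessed volume + stage-1 mask.

    Voxels outside the stage-1 mask are zeroed in a final masking step.
    """
    if v.shape != spine_mask.shape:
        raise ValueError(
            f"volume {v.shape} and mask {spine_mask.shape} are misaligned")
    mask = (spine_mask.data > 0)
    x = np.stack([v.data, mask]).astype(np.float32)
    with nn.no_grad():
        logits = model(x)
        probs = nn.softmax(logits, axis=1)
    labels = probs.data[0].argmax(axis=0).astype(np.int16)
    labels[~mask] = 0
    return LabelMap(labels, v.affine)
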