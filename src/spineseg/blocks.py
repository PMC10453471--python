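"""Reusable network blocks: residual block, attention gate, ASPP, CHASPP,
inverted residual bottleneck.

All blocks preserve spatial extents except the inverted residual at stride 2.
``norm=True`` (the default) follows every convolution with batch
normalization and drops the conv bias; ``norm=False`` gives plain biased
convolutions, which is the variant whose parameter count has a simple closed
form (two 3x3 convs at width C with identity shortcut: 2*(9*C^2 + C)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


def _conv_bn(cin, cout, k, rng, norm, stride=1, dilation=1, groups=1):
    layers = [nn.Conv2d(cin, cout, k, rng, stride=stride, dilation=dilation,
                        groups=groups, bias=not norm)]
    if norm:
        layers.append(nn.BatchNorm(cout))
    return layers


class ConvBlock2d(nn.Module):
    """conv3x3 -> [BN] -> ReLU, twice (the plain U-Net block)."""

    def __init__(self, cin: int, cout: int, rng, norm: bool = True):
        super().__init__()
        self.stack = nn.Sequential(*_conv_bn(cin, cout, 3, rng, norm))
        self.stack2 = nn.Sequential(*_conv_bn(cout, cout, 3, rng, norm))

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.stack2(nn.relu(self.stack(x))))


class ResidualBlock(nn.Module):
    """Two 3x3 convs with a shortcut path: out = relu(convs(x) + shortcut(x)).

    The shortcut is the identity when channel counts match, else a 1x1
    projection.  Spatial extents are preserved.
    """

    def __init__(self, cin: int, cout: int, rng, norm: bool = True):
        super().__init__()
        self.path1 = nn.Sequential(*_conv_bn(cin, cout, 3, rng, norm))
        self.path2 = nn.Sequential(*_conv_bn(cout, cout, 3, rng, norm))
        if cin == cout:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Sequential(*_conv_bn(cin, cout, 1, rng, norm))

    def forward(self, x: Tensor) -> Tensor:
        h = self.path2(nn.relu(self.path1(x)))
        return nn.relu(h + self.shortcut(x))


class AttentionGate(nn.Module):
    """Gated skip connection.

    Per spatial position x the decoder state (gate) is projected to a query
    q(x) and the skip features to a key k(x) and value v(x); the raw score is
    the dot product e(x) = q(x)·k(x), the attention weight is
    alpha(x) = logistic(e(x)) in (0, 1), and the output is alpha(x)·v(x).
    The output keeps the skip's spatial extents and channel count.
    """

    def __init__(self, skip_channels: int, gate_channels: int, rng,
                 inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(skip_channels // 2, 1)
        self.to_q = nn.Conv2d(gate_channels, inter, 1, rng)
        self.to_k = nn.Conv2d(skip_channels, inter, 1, rng)
        self.to_v = nn.Conv2d(skip_channels, skip_channels, 1, rng)

    def attention(self, skip: Tensor, gate: Tensor) -> Tensor:
        """The weight map alpha in (0, 1), shape (N, 1, H, W)."""
        if gate.shape[2:] != skip.shape[2:]:
            if tuple(2 * g for g in gate.shape[2:]) == tuple(skip.shape[2:]):
                gate = nn.upsample2d(gate, 2)
            else:
                raise ValueError(
                    f"gate extents {gate.shape[2:]} incompatible with "
                    f"skip extents {skip.shape[2:]}")
        q = self.to_q(gate)
        k = self.to_k(skip)
        e = (q * k).sum(axis=1, keepdims=True)
        return nn.sigmoid(e)

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        alpha = self.attention(skip, gate)
        return self.to_v(skip) * alpha


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel 3x3 dilated convs (one per
    rate) plus a 1x1 branch, concatenated and projected to out_channels."""

    def __init__(self, cin: int, out_channels: int, rng,
                 rates: tuple[int, ...] = (1, 2, 4, 8),
                 branch_width: int | None = None, norm: bool = True):
        super().__init__()
        if not rates or any(r < 1 for r in rates):
            raise ValueError("rates must be a non-empty list of positive ints")
        self.rates = tuple(rates)
        width = branch_width or out_channels
        self.branches = [nn.Sequential(*_conv_bn(cin, width, 3, rng, norm,
                                                 dilation=r))
                         for r in self.rates]
        self.pointwise = nn.Sequential(*_conv_bn(cin, width, 1, rng, norm))
        self.project = nn.Sequential(
            *_conv_bn((len(self.rates) + 1) * width, out_channels, 1, rng, norm))

    def forward(self, x: Tensor) -> Tensor:
        outs = [nn.relu(b(x)) for b in self.branches]
        outs.append(nn.relu(self.pointwise(x)))
        return nn.relu(self.project(nn.concat(outs, axis=1)))


class CHASPP(nn.Module):
    """Cascaded hierarchical ASPP: one root 3x3 dilated conv feeding three
    parallel 3x3 dilated branches, densifying the sampling inside the
    composed receptive field; branch outputs are concatenated and projected.
    """

    def __init__(self, cin: int, out_channels: int, rng,
                 root_rate: int = 2, branch_rates: tuple[int, ...] = (1, 2, 3),
                 branch_width: int | None = None, norm: bool = True):
        super().__init__()
        if root_rate < 1 or not branch_rates or any(r < 1 for r in branch_rates):
            raise ValueError("dilation rates must be positive")
        width = branch_width or out_channels
        self.root = nn.Sequential(*_conv_bn(cin, width, 3, rng, norm,
                                            dilation=root_rate))
        self.branches = [nn.Sequential(*_conv_bn(width, width, 3, rng, norm,
                                                 dilation=r))
                         for r in branch_rates]
        self.project = nn.Sequential(
            *_conv_bn(len(branch_rates) * width, out_channels, 1, rng, norm))

    def forward(self, x: Tensor) -> Tensor:
        root = nn.relu(self.root(x))
        outs = [nn.relu(b(root)) for b in self.branches]
        return nn.relu(self.project(nn.concat(outs, axis=1)))


@dataclass(frozen=True)
class BottleneckSpec:
    """One inverted-residual stage: expansion t, output channels c,
    repeats n, first-repeat stride a."""

    t: int
    c: int
    n: int = 1
    a: int = 1

    def __post_init__(self):
        if self.t < 1 or self.c < 1 or self.n < 1 or self.a not in (1, 2):
            raise ValueError(f"invalid bottleneck spec {self}")


class _InvertedResidualUnit(nn.Module):
    """expand 1x1 -> depthwise 3x3 (stride a) -> linear 1x1 projection."""

    def __init__(self, cin: int, cout: int, t: int, stride: int, rng,
                 norm: bool = True):
        super().__init__()
        hidden = cin * t
        self.use_shortcut = stride == 1 and cin == cout
        layers = []
        if t > 1:
            layers += _conv_bn(cin, hidden, 1, rng, norm)
        self.expand = nn.Sequential(*layers) if layers else None
        self.depthwise = nn.Sequential(*_conv_bn(
            hidden, hidden, 3, rng, norm, stride=stride, groups=hidden))
        self.project = nn.Sequential(*_conv_bn(hidden, cout, 1, rng, norm))

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.expand(x)) if self.expand is not None else x
        h = nn.relu(self.depthwise(h))
        h = self.project(h)  # linear: no activation on the projection
        if self.use_shortcut:
            h = h + x
        return h


class InvertedResidual(nn.Module):
    """A stage of n repeated bottleneck units; stride only in the first."""

    def __init__(self, cin: int, spec: BottleneckSpec, rng, norm: bool = True):
        super().__init__()
        units = []
        c_prev = cin
        for i in range(spec.n):
            units.append(_InvertedResidualUnit(
                c_prev, spec.c, spec.t, spec.a if i == 0 else 1, rng, norm))
            c_prev = spec.c
        self.units = units
        self.out_channels = spec.c

    def forward(self, x: Tensor) -> Tensor:
        for u in self.units:
            x = u(x)
        return x


def enumerate_parameters(module: nn.Module) -> list[tuple[str, tuple[int, ...]]]:
    """Brute-force per-layer walk: (name, shape) of every trainable array."""
    return [(name, tuple(p.data.shape))
            for name, p in module.named_parameters() if p.requires_grad]


def count_parameters(module: nn.Module) -> int:
    """Number of independently trainable scalars in a model."""
    return module.count_parameters()
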