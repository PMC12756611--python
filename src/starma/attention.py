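"""Star-shaped multi-scale attention (StarMA).

The block re-weights a rank-4 feature map (B, C, H, W) without changing its
shape.  Channels are split into G groups processed in parallel (folded into the
batch axis); each group runs two branches:

* **CCIB** — cross-channel information interaction: directional average pooling
  produces a per-height descriptor ``x_h`` (mean over width) and a per-width
  descriptor ``x_w`` (mean over height); a *star-shape structure* concatenates
  the two descriptors into one length ``H+W`` strip, downsamples it with a
  stride-2 1x1 convolution, forms the star product ``conv(z) * GELU(conv(z))``,
  squashes with a sigmoid and upsamples back, yielding broadcastable gates.
  The branch output is
  ``x1 = x_group * sigmoid(x_h) * sigmoid(x_w) * gate_h * gate_w``.
* **SCB** — stacked convolution branch: 1x1 -> 5x5 -> 7x7 same-padded
  convolutions followed by GELU, ``x2``.

**CSFA** fuses the branches: channel-softmax descriptors of each branch are
matrix-multiplied with the other branch's spatial map, the two resulting
spatial maps are summed, passed through a sigmoid and used to gate the grouped
input.  Every gate is a sigmoid output, so the block strictly attenuates:
``|out| <= |in|`` elementwise, with equality only where the input is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor
from .errors import ConfigurationError, ContractError, DegenerateInputError

__all__ = [
    "StarMAConfig",
    "GroupedFeatureMap",
    "AxialDescriptorPair",
    "StarGatePair",
    "BranchOutputs",
    "CrossSpatialMaps",
    "group_features",
    "ungroup_features",
    "axial_pool",
    "StarStructure",
    "StackedConvBranch",
    "StarMA",
]


@dataclass
class StarMAConfig:
    """Hyperparameters of the attention block.

    groups: number of channel groups G (each group holds C/G channels).
    scb_kernels: kernel sizes of the stacked convolution branch, in
        application order.
    star_upsample: interpolation used to restore the downsampled gate strip
        to length H+W ("nearest" or "linear").
    gn_groups: normalization groups for the CSFA GroupNorm; ``None`` means one
        group per channel (per-channel spatial normalization).
    seed: weight-initialization seed.
    """

    groups: int = 8
    scb_kernels: tuple[int, ...] = (1, 5, 7)
    star_upsample: str = "nearest"
    gn_groups: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.scb_kernels = tuple(self.scb_kernels)
        if self.groups < 1:
            raise ConfigurationError(f"groups must be >= 1, got {self.groups}")
        if self.star_upsample not in ("nearest", "linear"):
            raise ConfigurationError(
                f"star_upsample must be 'nearest' or 'linear', got {self.star_upsample!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scb_kernels"] = list(self.scb_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StarMAConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GroupedFeatureMap:
    """(B*G, C/G, H, W) view of a feature map split into G channel groups."""

    values: Tensor
    groups: int
    original_channels: int


@dataclass
class AxialDescriptorPair:
    """Directional pooled descriptors: x_h (N, C', H, 1) and x_w (N, C', 1, W)."""

    x_h: Tensor
    x_w: Tensor


@dataclass
class StarGatePair:
    """Sigmoid gates from the star-shape structure, broadcastable over W and H."""

    gate_h: Tensor
    gate_w: Tensor


@dataclass
class BranchOutputs:
    x1: Tensor
    x2: Tensor


@dataclass
class CrossSpatialMaps:
    x11: Tensor
    x22: Tensor
    x12: Tensor
    x21: Tensor
    weight: Tensor


# ---------------------------------------------------------------------------
# stateless operations
# ---------------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def group_features(x, groups: int) -> GroupedFeatureMap:
    """Split channels into `groups` contiguous groups folded into the batch axis.

    Channel k of group g corresponds to source channel ``g * (C/G) + k``.
    """
    x = _as_tensor(x)
    b, c, h, w = x.shape
    if c % groups:
        raise ConfigurationError(
            f"channel count C={c} is not divisible by groups G={groups}")
    values = x.reshape((b * groups, c // groups, h, w))
    return GroupedFeatureMap(values=values, groups=groups, original_channels=c)


def ungroup_features(grouped: GroupedFeatureMap) -> Tensor:
    """Inverse of :func:`group_features` (bit-exact round trip)."""
    n, cp, h, w = grouped.values.shape
    b = n // grouped.groups
    return grouped.values.reshape((b, grouped.original_channels, h, w))


def axial_pool(xg: GroupedFeatureMap | Tensor) -> AxialDescriptorPair:
    """Directional average pooling.

    ``x_h[b, c, h, 0]`` is the mean over the width axis of row h;
    ``x_w[b, c, 0, w]`` is the mean over the height axis of column w.
    """
    v = xg.values if isinstance(xg, GroupedFeatureMap) else _as_tensor(xg)
    return AxialDescriptorPair(
        x_h=v.mean(axis=3, keepdims=True),
        x_w=v.mean(axis=2, keepdims=True),
    )


# ---------------------------------------------------------------------------
# parametric sub-modules
# ---------------------------------------------------------------------------

class StarStructure(nn.Module):
    """Concatenate the axial descriptors, downsample, star-multiply, gate.

    The (N, C', H, 1) and (N, C', 1, W) descriptors are joined into a
    (N, C', H+W, 1) strip; a 1x1 convolution with stride 2 along the strip
    halves its length; two parallel 1x1 convolutions (one through GELU) are
    multiplied elementwise — the star operation, an implicit lift to a
    high-dimensional nonlinear feature space — then a sigmoid and an upsample
    back to length H+W produce the gate strip, split at H into gate_h/gate_w.
    """

    def __init__(self, channels: int, upsample: str = "nearest",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.upsample = upsample
        self.down = nn.Conv2d(channels, channels, 1, stride=(2, 1), rng=rng)
        self.proj_a = nn.Conv2d(channels, channels, 1, rng=rng)
        self.proj_b = nn.Conv2d(channels, channels, 1, rng=rng)

    def forward(self, x_h: Tensor, x_w: Tensor) -> StarGatePair:
        h = x_h.shape[2]
        w = x_w.shape[3]
        if h + w < 2:
            raise DegenerateInputError(f"strip length H+W={h + w} too short")
        strip = F.concatenate([x_h, x_w.transpose((0, 1, 3, 2))], axis=2)
        z = self.down(strip)
        gate = F.sigmoid(self.proj_a(z) * F.gelu(self.proj_b(z)))
        gate = F.resize1d(gate, h + w, axis=2, mode=self.upsample)
        gate_h = gate[:, :, :h, :]
        gate_w = gate[:, :, h:, :].transpose((0, 1, 3, 2))
        return StarGatePair(gate_h=gate_h, gate_w=gate_w)


class StackedConvBranch(nn.Module):
    """1x1 -> 5x5 -> 7x7 same-padded convolutions followed by GELU."""

    def __init__(self, channels: int, kernels: tuple[int, ...] = (1, 5, 7),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.convs = nn.ModuleList([
            nn.Conv2d(channels, channels, k, padding=k // 2, rng=rng)
            for k in kernels
        ])

    def forward(self, xg: GroupedFeatureMap | Tensor) -> Tensor:
        x = xg.values if isinstance(xg, GroupedFeatureMap) else _as_tensor(xg)
        for conv in self.convs:
            x = conv(x)
        return F.gelu(x)


class StarMA(nn.Module):
    """The full attention block: group -> (CCIB || SCB) -> CSFA -> ungroup.

    Ablation flags rewire the fusion without touching parameter layout (all
    branches are always constructed, so weight streams are identical across
    flag settings and a disabled factor is *removed* rather than re-learned):

    * ``use_sss=False`` drops the star gates from the CCIB product.
    * ``use_csfa=False`` fuses with ``sigmoid(x1 + x2) * x_group`` (or the
      single enabled branch: ``sigmoid(x1) * x_group`` for CCIB alone, and the
      channel-pooled softmax-weighted map ``sigmoid(x22 @ x2) * x_group`` for
      SCB alone).
    * CSFA requires both branches; at least one branch must stay enabled.
    """

    def __init__(self, channels: int, cfg: StarMAConfig | None = None, *,
                 use_ccib: bool = True, use_sss: bool = True,
                 use_scb: bool = True, use_csfa: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or StarMAConfig()
        if channels % cfg.groups:
            raise ConfigurationError(
                f"channel count C={channels} is not divisible by groups G={cfg.groups}")
        if not (use_ccib or use_scb):
            raise ConfigurationError("at least one attention branch must be enabled")
        if use_csfa and not (use_ccib and use_scb):
            raise ConfigurationError("CSFA fusion requires both branches enabled")
        self.cfg = cfg
        self.channels = channels
        self.grouped_channels = channels // cfg.groups
        self.use_ccib, self.use_sss = use_ccib, use_sss
        self.use_scb, self.use_csfa = use_scb, use_csfa
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        cp = self.grouped_channels
        self.star = StarStructure(cp, cfg.star_upsample, rng=rng)
        self.scb = StackedConvBranch(cp, cfg.scb_kernels, rng=rng)
        self.gn = nn.GroupNorm(cfg.gn_groups or cp, cp)

    # -- branch computations ---------------------------------------------
    def ccib(self, xg: GroupedFeatureMap) -> Tensor:
        """x1 = x_group * sigmoid(x_h) * sigmoid(x_w) [* gate_h * gate_w]."""
        axial = axial_pool(xg)
        x1 = xg.values * F.sigmoid(axial.x_h) * F.sigmoid(axial.x_w)
        if self.use_sss:
            gates = self.star(axial.x_h, axial.x_w)
            x1 = x1 * gates.gate_h * gates.gate_w
        return x1

    def csfa_maps(self, x1: Tensor, x2: Tensor) -> CrossSpatialMaps:
        """Mutual channel-softmax x spatial-map products (scale fusion)."""
        if x1.shape != x2.shape:
            raise ContractError(f"branch shape mismatch: {x1.shape} vs {x2.shape}")
        n, c, h, w = x1.shape
        x11 = F.softmax(self.gn(x1).mean(axis=(2, 3)).reshape((n, 1, c)), axis=2)
        x22 = F.softmax(x2.mean(axis=(2, 3)).reshape((n, 1, c)), axis=2)
        x12 = F.matmul(x11, x2.reshape((n, c, h * w))).reshape((n, 1, h, w))
        x21 = F.matmul(x22, x1.reshape((n, c, h * w))).reshape((n, 1, h, w))
        return CrossSpatialMaps(x11=x11, x22=x22, x12=x12, x21=x21,
                                weight=x12 + x21)

    def csfa(self, x1: Tensor, x2: Tensor, xg: GroupedFeatureMap) -> Tensor:
        if x1.shape != xg.values.shape:
            raise ContractError(
                f"branch/input shape mismatch: {x1.shape} vs {xg.values.shape}")
        maps = self.csfa_maps(x1, x2)
        return F.sigmoid(maps.weight) * xg.values

    # -- full forward ------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        x = _as_tensor(x)
        xg = group_features(x, self.cfg.groups)
        x1 = self.ccib(xg) if self.use_ccib else None
        x2 = self.scb(xg) if self.use_scb else None
        if self.use_csfa:
            out = self.csfa(x1, x2, xg)
        elif x1 is not None and x2 is not None:
            out = F.sigmoid(x1 + x2) * xg.values
        elif x1 is not None:
            out = F.sigmoid(x1) * xg.values
        else:
            # SCB-only fusion: channel-pooled softmax descriptor of x2 weights
            # its own spatial map, then gates the input.
            n, c, h, w = x2.shape
            x22 = F.softmax(x2.mean(axis=(2, 3)).reshape((n, 1, c)), axis=2)
            wmap = F.matmul(x22, x2.reshape((n, c, h * w))).reshape((n, 1, h, w))
            out = F.sigmoid(wmap) * xg.values
        return ungroup_features(
            GroupedFeatureMap(out, xg.groups, xg.original_channels))
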