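"""StarMA Net: the image-classification backbone built around the attention block.

Layout (spatial sizes for a 224x224 input):

* input stream — two 3x3 convolutions (the first with stride 2; 224 -> 112)
  followed by three Base Blocks, each ``conv3x3 -> BN -> GELU -> maxpool2x2 ->
  DropPath`` (112 -> 56 -> 28 -> 14): four stages of resolution reduction.
* intermediate layers — four StarMA Blocks at constant width and 14x14
  resolution.  Each block computes
  ``x_a = conv3x3(GELU(StarMA(BN(conv3x3(conv3x3(x))))))``, adds the residual
  ``x_attn = DropPath(x_a) + x``, applies a 1x1-convolution MLP expanding by
  ``mlp_ratio`` and closes with ``GELU(DropPath(M) + x_attn)``.
* output stream — a Normal Block (Base Block without pooling/DropPath), a 3x3
  stride-2 convolution (14 -> 7), a 1x1 convolution, BatchNorm, GELU, global
  average pooling and a fully connected classifier head.

The default widths are calibrated once so that the full model's parameter and
multiply-accumulate budget lands on the published figures (47.5M / 18.11G at
224^2); see the complexity module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor
from .attention import StarMA, StarMAConfig
from .errors import ConfigurationError, ContractError, DegenerateInputError

__all__ = ["BackboneConfig", "BaseBlock", "NormalBlock", "StarMABlock",
           "StarMANet", "build_starma_net", "apply_ablation"]


@dataclass
class BackboneConfig:
    """All architecture hyperparameters, ablation switches and width scaling."""

    stem_widths: tuple[int, int] = (80, 128)
    stage_widths: tuple[int, int, int] = (240, 352, 512)
    trunk_width: int = 512
    mlp_ratio: float = 4.0
    out_widths: tuple[int, int] = (784, 984)
    num_classes: int = 2
    drop_path: float = 0.0
    width_multiplier: float = 1.0
    use_ccib: bool = True
    use_sss: bool = True
    use_scb: bool = True
    use_csfa: bool = True
    starma: StarMAConfig = field(default_factory=StarMAConfig)

    def __post_init__(self):
        self.stem_widths = tuple(self.stem_widths)
        self.stage_widths = tuple(self.stage_widths)
        self.out_widths = tuple(self.out_widths)
        if isinstance(self.starma, dict):
            self.starma = StarMAConfig.from_dict(self.starma)
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        if not 0.0 <= self.drop_path < 1.0:
            raise ConfigurationError(f"drop_path must be in [0,1), got {self.drop_path}")
        if self.width_multiplier <= 0:
            raise ConfigurationError("width_multiplier must be positive")

    # -- width scaling -----------------------------------------------------
    def _scale(self, w: int) -> int:
        if self.width_multiplier == 1.0:
            return w  # use configured widths verbatim (validated downstream)
        g = self.starma.groups
        return max(g, int(round(w * self.width_multiplier / g)) * g)

    def scaled_widths(self) -> dict:
        """Every width field after `width_multiplier`, rounded to multiples of G."""
        return {
            "stem": tuple(self._scale(w) for w in self.stem_widths),
            "stages": tuple(self._scale(w) for w in self.stage_widths),
            "trunk": self._scale(self.trunk_width),
            "out": tuple(self._scale(w) for w in self.out_widths),
            "mlp_hidden": int(round(self._scale(self.trunk_width) * self.mlp_ratio)),
        }

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stem_widths"] = list(self.stem_widths)
        d["stage_widths"] = list(self.stage_widths)
        d["out_widths"] = list(self.out_widths)
        d["starma"] = self.starma.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "BackboneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class BaseBlock(nn.Module):
    """conv3x3 -> BN -> GELU -> maxpool 2x2 stride 2 -> DropPath (halves H, W)."""

    def __init__(self, in_ch: int, out_ch: int, drop_path: float = 0.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)
        self.pool = nn.MaxPool2d(2, 2)
        self.drop = nn.DropPath(drop_path)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise DegenerateInputError(
                f"spatial size {x.shape[2]}x{x.shape[3]} too small to pool")
        return self.drop(self.pool(F.gelu(self.bn(self.conv(x)))))


class NormalBlock(nn.Module):
    """conv3x3 -> BN -> GELU at constant resolution (refinement, no resize)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return F.gelu(self.bn(self.conv(x)))


class StarMABlock(nn.Module):
    """Residual attention block: attention branch + MLP branch, both DropPath-guarded."""

    def __init__(self, channels: int, mlp_hidden: int, starma_cfg: StarMAConfig,
                 drop_path: float = 0.0, *, use_ccib=True, use_sss=True,
                 use_scb=True, use_csfa=True, rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)
        self.attn = StarMA(channels, starma_cfg, use_ccib=use_ccib,
                           use_sss=use_sss, use_scb=use_scb, use_csfa=use_csfa,
                           rng=rng)
        self.conv3 = nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.mlp_up = nn.Conv2d(channels, mlp_hidden, 1, rng=rng)
        self.mlp_down = nn.Conv2d(mlp_hidden, channels, 1, rng=rng)
        self.drop_attn = nn.DropPath(drop_path)
        self.drop_mlp = nn.DropPath(drop_path)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ContractError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        x_a = self.conv3(F.gelu(self.attn(self.bn(self.conv2(self.conv1(x))))))
        x_attn = self.drop_attn(x_a) + x
        m = self.mlp_down(F.gelu(self.mlp_up(x_attn)))
        return F.gelu(self.drop_mlp(m) + x_attn)


class StarMANet(nn.Module):
    """The full classifier.  ``forward`` optionally captures named intermediate
    activations (used by Grad-CAM)."""

    def __init__(self, cfg: BackboneConfig):
        super().__init__()
        self.cfg = cfg
        widths = cfg.scaled_widths()
        s1, s2 = widths["stem"]
        w1, w2, w3 = widths["stages"]
        trunk = widths["trunk"]
        o1, o2 = widths["out"]
        if w3 != trunk:
            raise ConfigurationError(
                f"last stage width {w3} must equal trunk width {trunk}")
        g = cfg.starma.groups
        for w in (s1, s2, w1, w2, trunk, o1, o2):
            if w % g:
                raise ConfigurationError(
                    f"width {w} is not divisible by attention groups G={g}")
        rng = np.random.default_rng(cfg.starma.seed)
        flags = dict(use_ccib=cfg.use_ccib, use_sss=cfg.use_sss,
                     use_scb=cfg.use_scb, use_csfa=cfg.use_csfa)
        self.stem1 = nn.Conv2d(3, s1, 3, stride=2, padding=1, rng=rng)
        self.stem2 = nn.Conv2d(s1, s2, 3, padding=1, rng=rng)
        self.base1 = BaseBlock(s2, w1, cfg.drop_path, rng=rng)
        self.base2 = BaseBlock(w1, w2, cfg.drop_path, rng=rng)
        self.base3 = BaseBlock(w2, trunk, cfg.drop_path, rng=rng)
        self.starma_blocks = nn.ModuleList([
            StarMABlock(trunk, widths["mlp_hidden"], cfg.starma,
                        cfg.drop_path, rng=rng, **flags)
            for _ in range(4)
        ])
        self.normal = NormalBlock(trunk, trunk, rng=rng)
        self.down = nn.Conv2d(trunk, o1, 3, stride=2, padding=1, rng=rng)
        self.proj = nn.Conv2d(o1, o2, 1, rng=rng)
        self.out_bn = nn.BatchNorm2d(o2)
        self.fc = nn.Linear(o2, cfg.num_classes, rng=rng)

    def forward(self, x: Tensor, capture: dict | None = None) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        x = F.gelu(self.stem1(x))
        x = F.gelu(self.stem2(x))
        if capture is not None:
            capture["stem"] = x
        for name in ("base1", "base2", "base3"):
            x = getattr(self, name)(x)
            if capture is not None:
                capture[name] = x
        for i, blk in enumerate(self.starma_blocks):
            x = blk(x)
            if capture is not None:
                capture[f"starma_blocks.{i}"] = x
        x = self.normal(x)
        if capture is not None:
            capture["normal"] = x
        x = self.down(x)
        if capture is not None:
            capture["down"] = x
        x = F.gelu(self.out_bn(self.proj(x)))
        x = x.mean(axis=(2, 3))
        return self.fc(x)


def build_starma_net(cfg: BackboneConfig | None = None) -> StarMANet:
    """Construct StarMA Net from a config (reference widths by default)."""
    return StarMANet(cfg or BackboneConfig())


def apply_ablation(cfg: BackboneConfig) -> StarMANet:
    """Build the model variant selected by the config's ablation flags.

    With every flag enabled this is exactly the full model (the attention
    block always constructs all branch parameters, so weight streams match
    bit-for-bit across flag settings).
    """
    return build_starma_net(cfg)
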