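"""Parameter and multiply-accumulate accounting, plus the channel-coupling proxy.

Counting convention
-------------------
"FLOPs" figures in model-complexity tables of this literature are
multiply-accumulate (MAC) counts: one fused multiply-add is one unit, and only
convolution and fully connected layers are counted — normalization,
activations, pooling, softmax and the attention matrix products are excluded.
Under this convention the standard VGG19 and ResNet34 at 224x224 land on their
widely printed 19.63G / 3.7G budgets, which is how the convention is
cross-checked (see :mod:`starma.reference_models`).

Counts are structural: they depend only on tensor shapes, never on parameter
values, and are independent of batch size (reported per single input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import layers as _layers
from .nn.autodiff import Tensor, no_grad
from .nn.module import Module
from .errors import InputError

__all__ = ["LayerCost", "ComplexityReport", "Profiler", "profile",
           "count_params", "count_macs", "channel_coupling_proxy",
           "collect_channel_weights"]


@dataclass
class LayerCost:
    name: str
    kind: str
    params: int
    macs: int


@dataclass
class ComplexityReport:
    per_layer: list[LayerCost]
    total_params: int
    total_macs: int
    input_size: tuple[int, int, int]  # (H, W, channels)

    def to_dict(self) -> dict:
        return {
            "input_size": list(self.input_size),
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "per_layer": [[c.name, c.kind, c.params, c.macs] for c in self.per_layer],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def format_table(self) -> str:
        width = max([len(c.name) for c in self.per_layer] + [5])
        lines = [f"{'layer':<{width}}  {'kind':<6}  {'params':>12}  {'MACs':>14}"]
        for c in self.per_layer:
            lines.append(f"{c.name:<{width}}  {c.kind:<6}  {c.params:>12,}  {c.macs:>14,}")
        lines.append(f"{'total':<{width}}  {'':<6}  {self.total_params:>12,}  {self.total_macs:>14,}")
        lines.append(f"total params: {self.total_params/1e6:.2f}M   "
                     f"total MACs: {self.total_macs/1e9:.2f}G")
        return "\n".join(lines)


class Profiler:
    """Collects per-layer costs while a model runs.  With ``shapes_only`` the
    conv/linear layers skip their arithmetic and emit zero tensors of the
    correct shape, making tracing cheap at any resolution."""

    def __init__(self, model: Module, shapes_only: bool = True):
        self.names = {id(m): name for name, m in model.named_modules()}
        self.shapes_only = shapes_only
        self.records: list[LayerCost] = []

    def record(self, module: Module, kind: str, params: int, macs: int) -> None:
        name = self.names.get(id(module), module.__class__.__name__)
        self.records.append(LayerCost(name, kind, params, macs))

    def __enter__(self):
        _layers._ACTIVE_PROFILER = self
        return self

    def __exit__(self, *exc):
        _layers._ACTIVE_PROFILER = None


def profile(model: Module, input_size: tuple[int, int] = (224, 224),
            in_channels: int = 3, shapes_only: bool = True) -> ComplexityReport:
    """Trace one forward pass and return the per-layer cost report."""
    h, w = input_size
    was_training = model.training
    model.eval()
    try:
        with no_grad(), Profiler(model, shapes_only=shapes_only) as prof:
            model(Tensor(np.zeros((1, in_channels, h, w), dtype=np.float32)))
    finally:
        model.train(was_training)
    return ComplexityReport(
        per_layer=prof.records,
        total_params=count_params(model),
        total_macs=sum(c.macs for c in prof.records),
        input_size=(h, w, in_channels),
    )


def count_params(model: Module) -> int:
    """Total trainable parameter elements (incl. normalization affine terms)."""
    return int(sum(p.data.size for p in model.parameters()))


def count_macs(model: Module, input_size: tuple[int, int] = (224, 224),
               in_channels: int = 3) -> int:
    """Total conv+linear multiply-accumulates for one input of `input_size`."""
    return profile(model, input_size, in_channels).total_macs


# ---------------------------------------------------------------------------
# channel-interaction proxy
# ---------------------------------------------------------------------------

def channel_coupling_proxy(weights: np.ndarray) -> tuple[float, float]:
    """Summarize how strongly channels' attention weights co-vary.

    `weights` is an (n_samples, C) matrix of per-channel attention weights
    collected over a dataset.  Returns:

    * ``cci`` — mean absolute off-diagonal Pearson correlation between channel
      weight trajectories across samples (a documented coupling proxy; channels
      with zero variance contribute zero correlation);
    * ``weight_variance`` — mean per-sample variance of the channel weights.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] < 2:
        raise InputError("need a (n_samples >= 2, channels) weight matrix")
    n, c = w.shape
    weight_variance = float(w.var(axis=1).mean())
    if c < 2:
        return 0.0, weight_variance
    centered = w - w.mean(axis=0, keepdims=True)
    std = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (centered.T @ centered) / n / np.outer(std, std)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    off = corr[~np.eye(c, dtype=bool)]
    return float(np.abs(off).mean()), weight_variance


def collect_channel_weights(attn, x) -> np.ndarray:
    """Per-sample per-channel CCIB gate means from a StarMA block.

    Runs the block's cross-channel branch on `x` (B, C, H, W) and returns the
    spatial mean of the combined channel gate
    ``sigmoid(x_h) * sigmoid(x_w) [* gate_h * gate_w]`` as a (B, C) matrix —
    the quantity whose across-sample correlations the coupling proxy measures.
    """
    from .attention import axial_pool, group_features
    from .nn import functional as F

    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    b, c = x.shape[0], x.shape[1]
    with no_grad():
        xg = group_features(x, attn.cfg.groups)
        axial = axial_pool(xg)
        gate = F.sigmoid(axial.x_h).data * F.sigmoid(axial.x_w).data
        if attn.use_sss:
            gates = attn.star(axial.x_h, axial.x_w)
            gate = gate * gates.gate_h.data * gates.gate_w.data
    return gate.mean(axis=(2, 3)).reshape(b, c)
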