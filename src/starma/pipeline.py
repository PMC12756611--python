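"""Training, evaluation and Grad-CAM on image-folder or in-memory datasets.

The training protocol mirrors the evaluation setting the backbone was designed
for: cross-entropy loss, AdamW, batch size 16, inputs resized bilinearly and
scaled to [0,1] (no further standardization by default, no augmentation), the
checkpoint with the highest validation accuracy kept for testing.  Every
artifact written (checkpoint, report, heatmap) embeds the hash of the config
that produced it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import metrics as M
from .backbone import BackboneConfig, StarMANet, build_starma_net
from .errors import ConfigurationError, InputError
from .nn import AdamW, Adam
from .nn import functional as F
from .nn.autodiff import Tensor, no_grad
from .synthetic import LabeledImageSet

__all__ = ["TrainConfig", "EvalReport", "prepare_inputs", "train", "evaluate",
           "predict_proba", "gradcam", "save_checkpoint", "load_checkpoint",
           "recalibrate_batchnorm"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    epochs: int = 100
    optimizer: str = "adamw"        # prose protocol; "adam" kept as an option
    weight_decay: float = 0.01
    lr_schedule: str = "constant"   # "constant" (protocol) or "cosine"
    resize: tuple[int, int] = (224, 224)
    standardize: bool = False       # scale-to-[0,1] only by default
    seed: int = 0

    def __post_init__(self):
        self.resize = tuple(self.resize)
        if self.optimizer not in ("adam", "adamw"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ConfigurationError(f"unknown lr schedule {self.lr_schedule!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resize"] = list(self.resize)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def prepare_inputs(images: np.ndarray, size: tuple[int, int],
                   standardize: bool = False) -> np.ndarray:
    """(n, H, W[, 3]) pixels in [0,1] -> (n, 3, h, w) float32 model inputs.

    Grayscale images are replicated to three channels; resizing is bilinear.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None].repeat(3, axis=-1)
    n, h0, w0, _ = images.shape
    h, w = size
    if (h0, w0) != (h, w):
        resized = np.empty((n, h, w, 3), dtype=np.float32)
        for i in range(n):
            im = Image.fromarray((images[i] * 255).astype(np.uint8))
            resized[i] = np.asarray(im.resize((w, h), Image.BILINEAR),
                                    dtype=np.float32) / 255.0
        images = resized
    x = images.transpose(0, 3, 1, 2)
    if standardize:
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        sd = x.std(axis=(0, 2, 3), keepdims=True)
        x = (x - mu) / np.maximum(sd, 1e-6)
    return np.ascontiguousarray(x)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: StarMANet, path, meta: dict | None = None) -> None:
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    state["config_json"] = np.array(json.dumps(model.cfg.to_dict()))
    state["meta_json"] = np.array(json.dumps(
        dict(meta or {}, config_hash=model.cfg.config_hash())))
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[StarMANet, dict]:
    with np.load(path, allow_pickle=False) as data:
        cfg = BackboneConfig.from_dict(json.loads(str(data["config_json"])))
        meta = json.loads(str(data["meta_json"]))
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    model = build_starma_net(cfg)
    model.load_state_dict(state)
    return model, meta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def recalibrate_batchnorm(model: StarMANet, x: np.ndarray,
                          batch_size: int = 16) -> None:
    """Recompute BatchNorm running statistics as the plain average of batch
    statistics over `x` (a "precise BN" pass).

    With few optimizer steps per epoch the exponentially averaged statistics
    lag the fast-moving features and evaluation-mode accuracy becomes noisy;
    one recalibration pass before validation/checkpointing removes that.
    """
    from .nn.layers import BatchNorm2d

    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    saved_momentum = [b.momentum for b in bns]
    for b in bns:
        b._set_buffer("running_mean", np.zeros_like(b.running_mean))
        b._set_buffer("running_var", np.zeros_like(b.running_var))
    was_training = model.training
    model.train()
    try:
        with no_grad():
            for k, start in enumerate(range(0, x.shape[0], batch_size)):
                for b in bns:
                    b.momentum = 1.0 / (k + 1)  # cumulative moving average
                model(Tensor(x[start:start + batch_size]))
    finally:
        for b, m in zip(bns, saved_momentum):
            b.momentum = m
        model.train(was_training)


def _accuracy(model: StarMANet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    probs = predict_proba(model, x, batch_size=batch_size)
    return float((probs.argmax(axis=1) == y).mean())


def train(dataset: LabeledImageSet, backbone_cfg: BackboneConfig,
          train_cfg: TrainConfig, out_dir) -> dict:
    """Run the epoch loop; returns a summary dict (checkpoint path, history).

    `dataset` must carry a split assignment with a non-empty train split.  The
    best-validation-accuracy checkpoint is kept; without a validation split the
    final-epoch weights are saved instead.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tr = dataset.subset("train")
    if len(tr) == 0:
        raise ConfigurationError("empty training split")
    if len(set(dataset.class_names)) != backbone_cfg.num_classes:
        raise ConfigurationError(
            f"model head has {backbone_cfg.num_classes} classes but data has "
            f"{len(dataset.class_names)}")
    va = dataset.subset("val")
    x_tr = prepare_inputs(tr.images, train_cfg.resize, train_cfg.standardize)
    y_tr = tr.labels
    x_va = (prepare_inputs(va.images, train_cfg.resize, train_cfg.standardize)
            if len(va) else None)

    import dataclasses
    cfg = dataclasses.replace(
        backbone_cfg,
        starma=dataclasses.replace(backbone_cfg.starma, seed=train_cfg.seed))
    model = build_starma_net(cfg)
    params = model.parameters()
    if train_cfg.optimizer == "adamw":
        opt = AdamW(params, lr=train_cfg.learning_rate,
                    weight_decay=train_cfg.weight_decay)
    else:
        opt = Adam(params, lr=train_cfg.learning_rate)

    rng = np.random.default_rng(train_cfg.seed)
    ckpt_path = out_dir / "checkpoint.npz"
    log_path = out_dir / "train_log.jsonl"
    best_val = -1.0
    history = []
    with open(log_path, "w") as log:
        for epoch in range(train_cfg.epochs):
            t0 = time.time()
            if train_cfg.lr_schedule == "cosine":
                opt.lr = train_cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / train_cfg.epochs))
            model.train()
            order = rng.permutation(len(y_tr))
            losses = []
            for start in range(0, len(order), train_cfg.batch_size):
                idx = order[start:start + train_cfg.batch_size]
                logits = model(Tensor(x_tr[idx]))
                loss = F.cross_entropy(logits, y_tr[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            recalibrate_batchnorm(model, x_tr, train_cfg.batch_size)
            model.eval()
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "seconds": round(time.time() - t0, 2)}
            if x_va is not None:
                entry["val_accuracy"] = _accuracy(model, x_va, va.labels,
                                                  train_cfg.batch_size)
                if entry["val_accuracy"] >= best_val:
                    best_val = entry["val_accuracy"]
                    save_checkpoint(model, ckpt_path,
                                    {"epoch": epoch, "val_accuracy": best_val,
                                     "train": train_cfg.to_dict()})
            history.append(entry)
            log.write(json.dumps(entry) + "\n")
            log.flush()
            print(f"epoch {epoch:3d}  loss {entry['train_loss']:.4f}"
                  + (f"  val acc {entry['val_accuracy']:.4f}" if x_va is not None else "")
                  + f"  ({entry['seconds']}s)")
    if x_va is None:
        save_checkpoint(model, ckpt_path,
                        {"epoch": train_cfg.epochs - 1, "val_accuracy": None,
                         "train": train_cfg.to_dict()})
    return {"checkpoint": str(ckpt_path), "log": str(log_path),
            "history": history, "best_val_accuracy": best_val if best_val >= 0 else None,
            "model": model}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def predict_proba(model: StarMANet, images: np.ndarray,
                  resize: tuple[int, int] | None = None,
                  batch_size: int = 16) -> np.ndarray:
    """Deterministic softmax scores for raw (n, H, W[,3]) images."""
    if images.ndim == 4 and images.shape[1] == 3:
        x = np.asarray(images, dtype=np.float32)
    else:
        size = resize or images.shape[1:3]
        x = prepare_inputs(images, size)
    model.eval()
    out = []
    with no_grad():
        for start in range(0, x.shape[0], batch_size):
            logits = model(Tensor(x[start:start + batch_size]))
            out.append(F.softmax(logits, axis=1).data)
    return np.concatenate(out, axis=0)


@dataclass
class EvalReport:
    split: str
    metrics: M.MetricReport
    confusion: M.ConfusionMatrix
    auc_per_class: dict[str, float]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "metrics": self.metrics.to_dict(),
            "confusion": self.confusion.counts.tolist(),
            "class_labels": self.confusion.class_labels,
            "auc_per_class": self.auc_per_class,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(split=d["split"],
                   metrics=M.MetricReport(**d["metrics"]),
                   confusion=M.ConfusionMatrix(np.asarray(d["confusion"]),
                                               d["class_labels"]),
                   auc_per_class=d["auc_per_class"], meta=d["meta"])


def evaluate(model: StarMANet, dataset: LabeledImageSet, split_name: str,
             train_cfg: TrainConfig | None = None, out_dir=None,
             meta: dict | None = None) -> EvalReport:
    """Score one split: full metric report, confusion matrix, per-class ROC."""
    sub = dataset.subset(split_name)
    if len(sub) == 0:
        raise InputError(f"split {split_name!r} is empty")
    cfg = train_cfg or TrainConfig(resize=sub.images.shape[1:3])
    x = prepare_inputs(sub.images, cfg.resize, cfg.standardize)
    probs = predict_proba(model, x, batch_size=cfg.batch_size)
    y_pred = probs.argmax(axis=1)
    k = probs.shape[1]
    cm = M.confusion_matrix(sub.labels, y_pred, k, dataset.class_names)
    report = M.binary_metrics(cm) if k == 2 else M.multiclass_metrics(cm)
    curves = {}
    aucs = {}
    for c in range(k):
        try:
            curve = M.roc_curve((sub.labels == c).astype(int), probs[:, c])
            curves[dataset.class_names[c]] = curve
            aucs[dataset.class_names[c]] = curve.auc
        except InputError:
            aucs[dataset.class_names[c]] = float("nan")
    finite = [a for a in aucs.values() if np.isfinite(a)]
    report.auc = float(np.mean(finite)) if finite else None
    ev = EvalReport(split=split_name, metrics=report, confusion=cm,
                    auc_per_class=aucs,
                    meta=dict(meta or {}, config_hash=model.cfg.config_hash(),
                              n_samples=len(sub)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"eval_{split_name}.json", "w") as fh:
            json.dump(ev.to_dict(), fh, indent=1)
        report.to_csv(out_dir / f"metrics_{split_name}.csv")
        M.plot_confusion_matrix(cm, out_dir / f"confusion_{split_name}.png")
        if curves:
            M.plot_roc(curves, out_dir / f"roc_{split_name}.png")
            for name, curve in curves.items():
                curve.to_csv(out_dir / f"roc_{split_name}_{name}.csv")
    return ev


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(model: StarMANet, image: np.ndarray,
            target_layer: str = "starma_blocks.3",
            class_index: int | None = None,
            out_path=None) -> np.ndarray:
    """Gradient-weighted class-activation heatmap in [0,1] at input resolution.

    The gradient of the class score w.r.t. the target layer's activations is
    globally average-pooled into channel weights, the weighted activation sum
    is rectified, max-normalized and bilinearly upsampled to the input size.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        x = prepare_inputs(image[None], image.shape)
    elif image.ndim == 3 and image.shape[0] == 3:
        x = image[None]
    else:
        raise InputError(f"expected (H, W) or (3, H, W) image, got {image.shape}")
    h, w = x.shape[2], x.shape[3]
    model.eval()
    capture: dict[str, Tensor] = {}
    xt = Tensor(x, requires_grad=True)
    logits = model(xt, capture=capture)
    if target_layer not in capture:
        raise ConfigurationError(
            f"unknown target layer {target_layer!r}; available: {sorted(capture)}")
    if class_index is None:
        class_index = int(logits.data[0].argmax())
    score = logits[0, class_index]
    score.backward()
    act = capture[target_layer]
    if act.grad is None:
        cam = np.zeros(act.shape[2:], dtype=np.float32)
    else:
        weights = act.grad.mean(axis=(2, 3), keepdims=True)  # GAP of gradients
        cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
        peak = cam.max()
        cam = cam / peak if peak > 0 else np.zeros_like(cam)
    heat = np.asarray(
        Image.fromarray((cam * 255).astype(np.uint8), mode="L")
        .resize((w, h), Image.BILINEAR), dtype=np.float32) / 255.0
    if out_path is not None:
        _write_overlay(x[0], heat, out_path, model.cfg.config_hash())
    return heat


def _write_overlay(x: np.ndarray, heat: np.ndarray, out_path, cfg_hash: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(x.transpose(1, 2, 0), cmap="gray")
    ax.imshow(heat, cmap="jet", alpha=0.4)
    ax.set_axis_off()
    ax.set_title(f"config {cfg_hash}", fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
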