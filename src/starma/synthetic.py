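"""Deterministic synthetic lesion-image datasets.

Each image is a textured background carrying one elliptical "lesion" whose
geometry (radius, eccentricity), intensity contrast and internal texture
frequency are drawn from class-specific ranges, then corrupted with
multiplicative speckle (ultrasound-like) and additive Gaussian noise.  The
lesion mask is stored with every image, so localization checks (e.g. for
Grad-CAM heatmaps) have ground truth.  Classes are separable by construction:
the default three classes use disjoint radius ranges and distinct texture
frequencies, so a threshold on lesion size already classifies them.

Everything is driven by a single seed: the same spec + seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, InputError

__all__ = ["LesionClassParams", "SyntheticSpec", "LabeledImageSet",
           "generate", "split", "export_image_folder", "load_image_folder",
           "busi_like_spec"]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class LesionClassParams:
    """Geometry/appearance ranges for one class's lesions."""

    radius: tuple[float, float] = (8.0, 12.0)      # semi-major axis, px
    eccentricity: tuple[float, float] = (0.6, 1.0)  # semi-minor / semi-major
    contrast: float = 0.35                          # lesion minus background mean
    texture_freq: float = 0.0                       # cycles/px of lesion texture
    texture_amp: float = 0.0                        # texture amplitude

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radius"] = list(self.radius)
        d["eccentricity"] = list(self.eccentricity)
        return d


def _default_classes() -> list[LesionClassParams]:
    # Disjoint lesion-size bands plus distinct textures: with eccentricity in
    # (0.75, 1), the area ranges pi*a*b are ~[59, 201], [285, 616], [763, 1385]
    # px^2 — non-overlapping, so the classes are separable by lesion size alone.
    ecc = (0.75, 1.0)
    return [
        LesionClassParams(radius=(5, 8), eccentricity=ecc,
                          texture_freq=0.15, texture_amp=0.08),
        LesionClassParams(radius=(11, 14), eccentricity=ecc,
                          texture_freq=0.30, texture_amp=0.08),
        LesionClassParams(radius=(18, 21), eccentricity=ecc,
                          texture_freq=0.45, texture_amp=0.08),
    ]


@dataclass
class SyntheticSpec:
    """Parametric description of a dataset; `generate` materializes it."""

    n_classes: int = 3
    counts: tuple[int, ...] = (100, 100, 100)
    image_size: tuple[int, int] = (64, 64)
    classes: list[LesionClassParams] = field(default_factory=_default_classes)
    background_level: float = 0.35
    background_smooth_sigma: float = 6.0
    background_amp: float = 0.05
    speckle_var: float = 0.01
    gaussian_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        self.counts = tuple(self.counts)
        self.image_size = tuple(self.image_size)
        self.classes = [LesionClassParams(**c) if isinstance(c, dict) else c
                        for c in self.classes]
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if len(self.counts) != self.n_classes or len(self.classes) != self.n_classes:
            raise ConfigurationError(
                "counts and class parameter lists must have n_classes entries")
        if any(c < 1 for c in self.counts):
            raise ConfigurationError("every class needs at least one sample")
        h, w = self.image_size
        for k, cp in enumerate(self.classes):
            if 2 * cp.radius[1] > min(h, w):
                raise ConfigurationError(
                    f"class {k} lesion diameter {2 * cp.radius[1]} exceeds "
                    f"image size {self.image_size}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = list(self.counts)
        d["image_size"] = list(self.image_size)
        d["classes"] = [c.to_dict() for c in self.classes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(**d)


def busi_like_spec(seed: int = 0, image_size=(64, 64)) -> SyntheticSpec:
    """Three-class imbalance preset mirroring the published breast-ultrasound
    class counts (133 normal / 437 benign / 210 malignant)."""
    return SyntheticSpec(n_classes=3, counts=(133, 437, 210),
                         image_size=image_size, seed=seed)


@dataclass
class LabeledImageSet:
    """Materialized dataset: float images in [0,1], labels, lesion masks and
    (after :func:`split`) per-sample split assignment."""

    images: np.ndarray          # (n, H, W) float32
    labels: np.ndarray          # (n,) int64
    lesion_masks: np.ndarray    # (n, H, W) bool
    class_names: list[str]
    split_assignment: np.ndarray | None = None  # (n,) index into SPLIT_NAMES

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, split_name: str) -> "LabeledImageSet":
        if self.split_assignment is None:
            raise InputError("dataset has no split assignment")
        sel = self.split_assignment == SPLIT_NAMES.index(split_name)
        return LabeledImageSet(self.images[sel], self.labels[sel],
                               self.lesion_masks[sel], self.class_names)


def _make_image(rng: np.random.Generator, spec: SyntheticSpec,
                params: LesionClassParams) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_size
    # smooth textured background
    if spec.background_amp > 0:
        field_ = ndimage.gaussian_filter(rng.normal(size=(h, w)),
                                         spec.background_smooth_sigma)
        sd = field_.std()
        if sd > 0:
            field_ = field_ / sd * spec.background_amp
        bg = spec.background_level + field_
    else:
        bg = np.full((h, w), spec.background_level)
    # elliptical lesion
    a = rng.uniform(*params.radius)
    ecc = rng.uniform(*params.eccentricity)
    b = max(a * ecc, 1.0)
    theta = rng.uniform(0, np.pi)
    margin = a + 2
    cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
    cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img = bg + params.contrast * mask
    if params.texture_amp > 0 and params.texture_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tex = np.sin(2 * np.pi * params.texture_freq * u + phase)
        img = img + params.texture_amp * tex * mask
    # ultrasound-like multiplicative speckle + sensor noise
    if spec.speckle_var > 0:
        img = img * (1.0 + rng.normal(0, np.sqrt(spec.speckle_var), size=(h, w)))
    if spec.gaussian_sigma > 0:
        img = img + rng.normal(0, spec.gaussian_sigma, size=(h, w))
    if spec.speckle_var > 0 or spec.gaussian_sigma > 0:
        img = np.clip(img, 0.0, 1.0)
    return img.astype(np.float32), mask


def generate(spec: SyntheticSpec) -> LabeledImageSet:
    """Materialize the dataset described by `spec` (deterministic in spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    images, labels, masks = [], [], []
    for k in range(spec.n_classes):
        for _ in range(spec.counts[k]):
            img, mask = _make_image(rng, spec, spec.classes[k])
            images.append(img)
            labels.append(k)
            masks.append(mask)
    return LabeledImageSet(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        lesion_masks=np.stack(masks),
        class_names=[f"class{k}" for k in range(spec.n_classes)],
    )


def split(dataset: LabeledImageSet, ratios=(7, 1.5, 1.5),
          seed: int = 0) -> LabeledImageSet:
    """Stratified shuffle-split into train/val/test.

    Per class, the val and test sizes are ``round(fraction * n)`` and the
    remainder goes to train; splits are disjoint and exhaustive.  A class with
    fewer samples than populated splits goes entirely to train, with a warning.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) == 2:
        ratios = (ratios[0], 0.0, ratios[1])
    if len(ratios) != 3 or any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise InputError(f"need 2 or 3 non-negative ratios, got {ratios}")
    fracs = np.array(ratios) / sum(ratios)
    rng = np.random.default_rng(seed)
    assignment = np.zeros(len(dataset), dtype=np.int64)
    n_splits = int(np.count_nonzero(fracs))
    for k in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == k)
        rng.shuffle(idx)
        n = idx.size
        if n < n_splits:
            warnings.warn(f"class {k} has {n} samples < {n_splits} splits; "
                          "assigning all to train")
            assignment[idx] = 0
            continue
        n_val = int(round(fracs[1] * n))
        n_test = int(round(fracs[2] * n))
        n_train = n - n_val - n_test  # remainder-to-train rounding
        assignment[idx[:n_train]] = 0
        assignment[idx[n_train:n_train + n_val]] = 1
        assignment[idx[n_train + n_val:]] = 2
    return LabeledImageSet(dataset.images, dataset.labels, dataset.lesion_masks,
                           dataset.class_names, split_assignment=assignment)


# ---------------------------------------------------------------------------
# image-folder round trip
# ---------------------------------------------------------------------------

def export_image_folder(dataset: LabeledImageSet, path) -> Path:
    """Write ``<split>/<class>/<index>.png`` (8-bit grayscale) plus a parallel
    ``masks/`` tree; the layout any class-per-folder loader reads."""
    root = Path(path)
    if dataset.split_assignment is None:
        dataset = LabeledImageSet(dataset.images, dataset.labels,
                                  dataset.lesion_masks, dataset.class_names,
                                  np.zeros(len(dataset), dtype=np.int64))
    try:
        for i in range(len(dataset)):
            split_name = SPLIT_NAMES[dataset.split_assignment[i]]
            cls = dataset.class_names[dataset.labels[i]]
            img_dir = root / split_name / cls
            mask_dir = root / "masks" / split_name / cls
            img_dir.mkdir(parents=True, exist_ok=True)
            mask_dir.mkdir(parents=True, exist_ok=True)
            arr = np.clip(dataset.images[i] * 255.0 + 0.5, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(img_dir / f"{i:05d}.png")
            Image.fromarray(dataset.lesion_masks[i].astype(np.uint8) * 255,
                            mode="L").save(mask_dir / f"{i:05d}.png")
    except OSError as err:
        raise OSError(f"failed writing dataset under {root}: {err}") from err
    return root


def load_image_folder(path, split_name: str = "train",
                      class_names: list[str] | None = None,
                      with_masks: bool = False):
    """Read a ``<split>/<class>/*.png|jpg|tif`` tree back into arrays.

    Returns (images (n,H,W) float32 in [0,1], labels, class_names) and, with
    ``with_masks``, the parallel boolean mask stack (all-False where absent).
    """
    root = Path(path) / split_name
    if not root.is_dir():
        raise InputError(f"missing split directory {root}")
    names = class_names or sorted(p.name for p in root.iterdir() if p.is_dir())
    if not names:
        raise InputError(f"no class directories under {root}")
    images, labels, masks = [], [], []
    for k, cls in enumerate(names):
        for f in sorted((root / cls).iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                continue
            img = np.asarray(Image.open(f).convert("L"), dtype=np.float32) / 255.0
            images.append(img)
            labels.append(k)
            if with_masks:
                mf = Path(path) / "masks" / split_name / cls / f.name
                if mf.exists():
                    masks.append(np.asarray(Image.open(mf).convert("L")) > 127)
                else:
                    masks.append(np.zeros_like(img, dtype=bool))
    if not images:
        raise InputError(f"no images found under {root}")
    out = (np.stack(images), np.asarray(labels, dtype=np.int64), names)
    if with_masks:
        return out + (np.stack(masks),)
    return out
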