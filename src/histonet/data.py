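"""Dataset indexing, stratified splitting and the balanced training stream.

The pipeline consumes a BreakHis-style directory tree
(``magnification/class/image.png``), splits it 70/20/10 per class into
train/validation/test, and builds an oversampled, balanced training stream:

1. count images per class in the training split;
2. set a common per-class target of three times the largest class's count;
3. serve each class cyclically up to the target, augmenting minority
   classes (those smaller than the largest) with AugMix and every training
   image with geometric transforms.

Validation and test streams receive preprocessing and standardization
only — never balancing or geometric augmentation.

Split rounding is floor for train and floor for validation with the
remainder to test, per class; with the published BreakHis counts this
yields per-class balanced targets of 1812/1896/1881/1653 images at
40x/100x/200x/400x.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from PIL import Image

from . import stain
from .synthetic import BREAKHIS_CLASSES, BREAKHIS_MAGNIFICATIONS

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

# Channel statistics of the ImageNet corpus, the canonical standardization
# constants of ImageNet-pretrained backbones (images scaled to [0, 1]).
IMAGENET_CHANNEL_STATS_MEAN = (0.485, 0.456, 0.406)
IMAGENET_CHANNEL_STATS_STD = (0.229, 0.224, 0.225)


class LayoutError(ValueError):
    """The directory tree does not match the expected layout."""


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    label: str
    magnification: int
    split: str | None = None  # train | val | test


@dataclass
class DatasetIndex:
    """All images of one magnification, with per-class counts."""

    records: list
    per_class_counts: dict
    magnification: int
    classes: tuple = BREAKHIS_CLASSES

    def __post_init__(self) -> None:
        total = sum(self.per_class_counts.values())
        if total != len(self.records):
            raise ValueError("per_class_counts inconsistent with records")

    def subset(self, split: str) -> "DatasetIndex":
        recs = [r for r in self.records if r.split == split]
        counts = {c: 0 for c in self.classes}
        for r in recs:
            counts[r.label] += 1
        return DatasetIndex(recs, counts, self.magnification, self.classes)

    def paths_by_class(self) -> dict:
        out: dict = {c: [] for c in self.classes}
        for r in self.records:
            out[r.label].append(r.path)
        for c in out:
            out[c] = sorted(out[c])
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "label", "magnification", "split"])
            for r in self.records:
                w.writerow([str(r.path), r.label, r.magnification, r.split or ""])


def index_dataset(root, magnification: int, classes: Sequence[str] = BREAKHIS_CLASSES) -> DatasetIndex:
    """Enumerate ``root/<magnification>/<class>/*`` deterministically.

    Files are sorted lexicographically; non-image files are skipped by an
    extension whitelist.  A missing class directory or an empty class is a
    layout error naming the class.
    """
    root = Path(root)
    mag_dir = root / str(magnification)
    if not mag_dir.is_dir():
        raise LayoutError(f"no directory for magnification {magnification} under {root}")
    records = []
    counts = {}
    for cls in classes:
        cls_dir = mag_dir / cls
        if not cls_dir.is_dir():
            raise LayoutError(f"missing class directory: {cls!r} at {cls_dir}")
        files = sorted(
            p for p in cls_dir.iterdir()
            if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise LayoutError(f"class {cls!r} contains no images at {cls_dir}")
        counts[cls] = len(files)
        records.extend(
            ImageRecord(path=p, label=cls, magnification=magnification) for p in files
        )
    return DatasetIndex(records, counts, magnification, tuple(classes))


def split_counts(n: int, ratios: Sequence[float] = (0.7, 0.2, 0.1)) -> tuple:
    """Per-class train/val/test sizes: floor, floor, remainder."""
    train = math.floor(ratios[0] * n)
    val = math.floor(ratios[1] * n)
    return train, val, n - train - val


def stratified_split(
    index: DatasetIndex,
    ratios: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetIndex:
    """Assign train/val/test split labels per class, driven only by ``seed``.

    Within each class the sorted file list is shuffled with a seeded
    generator and cut at floor(r_train * n) and floor(r_val * n); the
    remainder is the test set.  The same (index, seed) always yields the
    same membership.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    by_class = index.paths_by_class()
    for cls, paths in by_class.items():
        if len(paths) < 3:
            raise ValueError(
                f"class {cls!r} has {len(paths)} images; need >= 3 to split"
            )
    rng = np.random.default_rng(seed)
    assigned = []
    for cls in index.classes:
        paths = by_class[cls]
        order = rng.permutation(len(paths))
        n_train, n_val, _ = split_counts(len(paths), ratios)
        for rank, idx in enumerate(order):
            split = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
            assigned.append(
                ImageRecord(paths[idx], cls, index.magnification, split)
            )
    counts = dict(index.per_class_counts)
    return DatasetIndex(assigned, counts, index.magnification, index.classes)


@dataclass(frozen=True)
class BalancePlan:
    """Oversampling targets for the balanced training stream.

    ``oversample_target`` is three times the largest training class;
    classes smaller than the largest are additionally augmented with
    AugMix (``augment_with_mix``); one epoch serves ``oversample_target``
    items from every class.
    """

    max_class_count: int
    oversample_target: int
    augment_with_mix: dict
    epoch_length: int
    class_counts: dict

    def __post_init__(self) -> None:
        if self.max_class_count <= 0:
            raise ValueError("max_class_count must be positive")
        if self.oversample_target != 3 * self.max_class_count:
            raise ValueError("oversample_target must be 3 x max_class_count")


def plan_balance(train_index: DatasetIndex) -> BalancePlan:
    """Derive the balancing plan from the training split's class counts."""
    counts = train_index.per_class_counts
    if not counts or all(v == 0 for v in counts.values()):
        raise ValueError("training split is empty; cannot plan balancing")
    if any(v == 0 for v in counts.values()):
        empty = [c for c, v in counts.items() if v == 0]
        raise ValueError(f"training split has empty classes: {empty}")
    max_count = max(counts.values())
    target = 3 * max_count
    return BalancePlan(
        max_class_count=max_count,
        oversample_target=target,
        augment_with_mix={c: counts[c] < max_count for c in counts},
        epoch_length=len(counts) * target,
        class_counts=dict(counts),
    )


# ---------------------------------------------------------------------------
# per-image operations


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel standardization constants for image tensors in [0, 1]."""

    mean: tuple = IMAGENET_CHANNEL_STATS_MEAN
    std: tuple = IMAGENET_CHANNEL_STATS_STD

    def __post_init__(self) -> None:
        if len(self.mean) != len(self.std):
            raise ValueError("mean and std must have equal length")
        if any(s <= 0 for s in self.std):
            raise ValueError("channel std must be strictly positive")


def standardize(image: np.ndarray, stats: ChannelStats = ChannelStats()) -> np.ndarray:
    """Per-channel (x - mu_c) / sigma_c on an H x W x C float tensor."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != len(stats.mean):
        raise ValueError(
            f"image has {image.shape} but stats cover {len(stats.mean)} channels"
        )
    mean = np.asarray(stats.mean, dtype=np.float64)
    std = np.asarray(stats.std, dtype=np.float64)
    return (image - mean) / std


def preprocess(
    image: np.ndarray,
    side: int = 384,
    target: stain.StainTarget | None = None,
) -> np.ndarray:
    """Resize (shorter side) + center-crop to ``side``, then stain-normalize.

    The output is an 8-bit RGB side x side x 3 array.  Stain normalization
    is applied when a target is configured.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    if (h, w) != (side, side):
        scale = side / min(h, w)
        nh, nw = max(side, int(round(h * scale))), max(side, int(round(w * scale)))
        pil = Image.fromarray(image.astype(np.uint8)).resize((nw, nh), Image.BILINEAR)
        image = np.asarray(pil)
        top = (nh - side) // 2
        left = (nw - side) // 2
        image = image[top : top + side, left : left + side]
    if target is not None:
        image = stain.normalize(image, target)
    return image.astype(np.uint8)


def _affine_matrix(angle, translate, scale, shear, center):
    """Inverse affine map (output -> input) for PIL, rotating about center."""
    a = math.radians(angle)
    s = math.radians(shear)
    cx, cy = center
    tx, ty = translate
    # forward map: scale * rotation * x-shear about the image center, then
    # the pixel translation; PIL wants the inverse (output -> input)
    cos_a, sin_a = math.cos(a), math.sin(a)
    r = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
    sh = np.array([[1.0, math.tan(s)], [0.0, 1.0]])
    fwd = scale * (r @ sh)
    inv = np.linalg.inv(fwd)
    # output pixel p maps to input inv @ (p - center - t) + center
    off = np.array([cx + tx, cy + ty])
    b = -inv @ off + np.array([cx, cy])
    return (inv[0, 0], inv[0, 1], b[0], inv[1, 0], inv[1, 1], b[1])


@dataclass(frozen=True)
class GeometricParams:
    hflip: bool
    vflip: bool
    angle: float  # degrees
    translate: tuple  # fractions of width/height
    scale: float
    shear: float  # degrees

    def is_identity(self) -> bool:
        return (
            not self.hflip
            and not self.vflip
            and self.angle == 0.0
            and self.translate == (0.0, 0.0)
            and self.scale == 1.0
            and self.shear == 0.0
        )


def draw_geometric_params(rng: np.random.Generator) -> GeometricParams:
    """Sample the augmentation parameters: flips p=0.5 each, rotation in
    [-45, 45] degrees, translation up to 10% per axis, scale in [0.8, 1.2],
    shear in [0, 10] degrees."""
    return GeometricParams(
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        angle=float(rng.uniform(-45.0, 45.0)),
        translate=(float(rng.uniform(-0.1, 0.1)), float(rng.uniform(-0.1, 0.1))),
        scale=float(rng.uniform(0.8, 1.2)),
        shear=float(rng.uniform(0.0, 10.0)),
    )


def geometric_transform(
    image: np.ndarray,
    rng: np.random.Generator | None = None,
    params: GeometricParams | None = None,
) -> np.ndarray:
    """Random flip / rotate / translate / scale / shear; dimensions preserved.

    Either an rng (parameters drawn internally) or explicit params may be
    given.  Identity parameters return the input unchanged.
    """
    if params is None:
        if rng is None:
            raise ValueError("provide either rng or params")
        params = draw_geometric_params(rng)
    image = np.asarray(image).astype(np.uint8)
    if params.is_identity():
        return image.copy()
    out = image
    if params.hflip:
        out = out[:, ::-1]
    if params.vflip:
        out = out[::-1, :]
    if params.angle != 0.0 or params.translate != (0.0, 0.0) or params.scale != 1.0 or params.shear != 0.0:
        h, w = out.shape[:2]
        mat = _affine_matrix(
            params.angle,
            (params.translate[0] * w, params.translate[1] * h),
            params.scale,
            params.shear,
            ((w - 1) / 2.0, (h - 1) / 2.0),
        )
        pil = Image.fromarray(np.ascontiguousarray(out))
        # fill exposed borders with the image's mean color: tissue fills the
        # frame, so black fill would inject artificial global-intensity shifts
        fill = tuple(int(round(v)) for v in out.reshape(-1, out.shape[-1]).mean(0))
        out = np.asarray(
            pil.transform((w, h), Image.AFFINE, mat, resample=Image.BILINEAR,
                          fillcolor=fill)
        )
    return out.copy()


# --- AugMix -----------------------------------------------------------------

def _augmix_ops(severity: int):
    """The AugMix chain operations at the given severity (0 => identity)."""
    from PIL import ImageOps

    lvl = severity / 10.0

    def rotate(img, rng):
        deg = rng.uniform(-30, 30) * lvl
        return img.rotate(deg, resample=Image.BILINEAR)

    def shear_x(img, rng):
        s = rng.uniform(-0.3, 0.3) * lvl
        return img.transform(img.size, Image.AFFINE, (1, s, 0, 0, 1, 0), Image.BILINEAR)

    def shear_y(img, rng):
        s = rng.uniform(-0.3, 0.3) * lvl
        return img.transform(img.size, Image.AFFINE, (1, 0, 0, s, 1, 0), Image.BILINEAR)

    def translate_x(img, rng):
        t = rng.uniform(-0.3, 0.3) * lvl * img.size[0]
        return img.transform(img.size, Image.AFFINE, (1, 0, t, 0, 1, 0), Image.BILINEAR)

    def translate_y(img, rng):
        t = rng.uniform(-0.3, 0.3) * lvl * img.size[1]
        return img.transform(img.size, Image.AFFINE, (1, 0, 0, 0, 1, t), Image.BILINEAR)

    def posterize(img, rng):
        bits = 8 - int(round(4 * lvl * rng.random()))
        return ImageOps.posterize(img, max(1, bits))

    def solarize(img, rng):
        thr = int(256 - 128 * lvl * rng.random())
        return ImageOps.solarize(img, thr)

    def autocontrast(img, rng):
        if lvl == 0:
            return img
        return ImageOps.autocontrast(img)

    def equalize(img, rng):
        if lvl == 0:
            return img
        return ImageOps.equalize(img)

    return [rotate, shear_x, shear_y, translate_x, translate_y,
            posterize, solarize, autocontrast, equalize]


def augmix(
    image: np.ndarray,
    rng: np.random.Generator,
    width: int = 3,
    depth: int = -1,
    severity: int = 3,
    dirichlet_alpha: float = 1.0,
) -> np.ndarray:
    """AugMix: blend ``width`` stochastic augmentation chains.

    Chain mixing weights are Dirichlet(alpha)-sampled (they sum to 1) and
    the blended image is convexly combined with the original via a
    Beta(alpha, alpha) weight, preserving the image's semantic content
    while diversifying its appearance.  ``depth`` < 0 draws a chain depth
    uniformly from {1, 2, 3}.  Severity 0 makes every chain the identity.
    """
    image = np.asarray(image).astype(np.uint8)
    ops = _augmix_ops(severity)
    ws = rng.dirichlet([dirichlet_alpha] * width)
    m = rng.beta(dirichlet_alpha, dirichlet_alpha)
    orig = image.astype(np.float64)
    mixed = np.zeros_like(orig)
    for i in range(width):
        chain = Image.fromarray(image)
        d = depth if depth > 0 else int(rng.integers(1, 4))
        for _ in range(d):
            op = ops[int(rng.integers(len(ops)))]
            chain = op(chain, rng)
        mixed += ws[i] * np.asarray(chain, dtype=np.float64)
    out = (1.0 - m) * orig + m * mixed
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# streams


def load_image(path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - surface the path
        raise IOError(f"cannot read image {path}: {exc}") from exc


@dataclass
class PipelineConfig:
    """Per-image processing configuration shared by all streams."""

    side: int = 384
    stain_target: stain.StainTarget | None = None
    channel_stats: ChannelStats = field(default_factory=ChannelStats)
    augmix_width: int = 3
    augmix_depth: int = -1
    augmix_severity: int = 3
    augmix_alpha: float = 1.0
    use_stain_norm: bool = True
    use_balance_aug: bool = True
    use_geometric_aug: bool = True

    def effective_target(self):
        return self.stain_target if self.use_stain_norm else None


class BalancedTrainStream:
    """The oversampled, balanced training stream.

    One epoch yields ``oversample_target`` items from each class: item i of
    class c is the (i mod class_count)-th image in sorted order, run through
    preprocess, AugMix balancing (minority classes only), the geometric
    transform and standardization.  Item order within an epoch is a seeded
    shuffle of the (class, i) grid.
    """

    def __init__(
        self,
        train_index: DatasetIndex,
        plan: BalancePlan,
        config: PipelineConfig,
        seed: int = 0,
    ) -> None:
        self.index = train_index
        self.plan = plan
        self.config = config
        self.seed = seed
        self.paths = train_index.paths_by_class()
        self.classes = list(train_index.classes)
        self.class_to_idx = {c: i for i, c in enumerate(self.classes)}

    def __len__(self) -> int:
        if not self.config.use_balance_aug:
            repeats = 3 if self.config.use_geometric_aug else 1
            return repeats * sum(self.plan.class_counts.values())
        return self.plan.epoch_length

    def get_item(self, cls: str, i: int, rng: np.random.Generator) -> tuple:
        """Load, balance-augment and transform item ``i`` of class ``cls``."""
        if not 0 <= i < self.plan.oversample_target:
            raise IndexError(
                f"epoch position {i} outside [0, {self.plan.oversample_target})"
            )
        paths = self.paths[cls]
        img = load_image(paths[i % len(paths)])
        img = preprocess(img, self.config.side, self.config.effective_target())
        if self.config.use_balance_aug and self.plan.augment_with_mix[cls]:
            img = augmix(
                img,
                rng,
                width=self.config.augmix_width,
                depth=self.config.augmix_depth,
                severity=self.config.augmix_severity,
                dirichlet_alpha=self.config.augmix_alpha,
            )
        if self.config.use_geometric_aug:
            img = geometric_transform(img, rng)
        x = standardize(img.astype(np.float64) / 255.0, self.config.channel_stats)
        return x, self.class_to_idx[cls]

    def epoch(self, epoch_index: int = 0) -> Iterator:
        """Iterate one epoch.

        With balancing on, every class is served exactly
        ``oversample_target`` times.  With the balance step ablated, no
        equalization happens: each class is served its own image count
        (tripled by the geometric transform when that is active), so the
        original imbalance is preserved.
        """
        rng = np.random.default_rng([self.seed, epoch_index])
        if self.config.use_balance_aug:
            grid = [(c, i) for c in self.classes
                    for i in range(self.plan.oversample_target)]
        else:
            repeats = 3 if self.config.use_geometric_aug else 1
            grid = [(c, i) for c in self.classes
                    for i in range(repeats * self.plan.class_counts[c])]
        order = rng.permutation(len(grid))
        for k in order:
            cls, i = grid[k]
            yield self.get_item(cls, int(i), rng)

    def batches(self, batch_size: int, epoch_index: int = 0) -> Iterator:
        xs, ys = [], []
        for x, y in self.epoch(epoch_index):
            xs.append(np.transpose(x, (2, 0, 1)))
            ys.append(y)
            if len(xs) == batch_size:
                yield np.stack(xs).astype(np.float32), np.array(ys)
                xs, ys = [], []
        if xs:
            yield np.stack(xs).astype(np.float32), np.array(ys)


class EvalStream:
    """Validation/test stream: preprocess + standardize only, no augmentation."""

    def __init__(self, index: DatasetIndex, config: PipelineConfig) -> None:
        self.index = index
        self.config = config
        self.classes = list(index.classes)
        self.class_to_idx = {c: i for i, c in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.index.records)

    def __iter__(self) -> Iterator:
        for rec in self.index.records:
            img = load_image(rec.path)
            img = preprocess(img, self.config.side, self.config.effective_target())
            x = standardize(img.astype(np.float64) / 255.0, self.config.channel_stats)
            yield x, self.class_to_idx[rec.label]

    def batches(self, batch_size: int) -> Iterator:
        xs, ys = [], []
        for x, y in self:
            xs.append(np.transpose(x, (2, 0, 1)))
            ys.append(y)
            if len(xs) == batch_size:
                yield np.stack(xs).astype(np.float32), np.array(ys)
                xs, ys = [], []
        if xs:
            yield np.stack(xs).astype(np.float32), np.array(ys)


def run_manifest(index: DatasetIndex, plan: BalancePlan, seed: int) -> dict:
    """JSON-serializable record of the prepared run (seeds, counts, plan)."""
    return {
        "magnification": index.magnification,
        "seed": seed,
        "per_class_counts": dict(index.per_class_counts),
        "total": len(index.records),
        "plan": {
            "max_class_count": plan.max_class_count,
            "oversample_target": plan.oversample_target,
            "epoch_length": plan.epoch_length,
            "augment_with_mix": dict(plan.augment_with_mix),
        },
    }
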