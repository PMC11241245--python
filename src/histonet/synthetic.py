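"""Synthetic H&E-like image fixtures in the BreakHis directory layout.

Real breast-tumor histopathology (the BreakHis corpus) is organized as
``magnification/class/image.png`` with eight tumor sub-types — benign
adenosis (A), fibroadenoma (F), phyllodes tumor (PT), tubular adenoma (TA)
and malignant ductal (DC), lobular (LC), mucinous (MC) and papillary (PC)
carcinoma — imaged at 40x/100x/200x/400x.  This module synthesizes small
stand-in datasets with the same layout so the full pipeline (indexing,
splitting, balancing, stain normalization, training, evaluation,
explanation) runs at desk scale without any download.

Each image is a pink eosin-like background scattered with purple
hematoxylin-like elliptical "nuclei"; the per-class blob density, size and
eccentricity ranges (and, in the color-coded mode, a per-class background
tint) make the classes statistically separable.  A global RGB cast can be
applied to emulate a lab-to-lab staining shift, which is what the Reinhard
normalization step is meant to remove.  The generator does not attempt
biologically realistic tissue texture: spatial arrangement, chromatin
structure and magnification semantics are absent, so results on these
fixtures exercise the machinery, not diagnostic performance.

Everything is driven by a single seed; a fixed spec + seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

BREAKHIS_CLASSES = ("A", "F", "PT", "TA", "DC", "LC", "MC", "PC")
BREAKHIS_MAGNIFICATIONS = (40, 100, 200, 400)

# Published per-class image counts of the BreakHis corpus, by magnification,
# in the class order above.  Used to regenerate the real corpus' imbalance.
BREAKHIS_CLASS_COUNTS = {
    40: (114, 253, 109, 149, 864, 156, 205, 145),
    100: (113, 260, 121, 150, 903, 170, 222, 142),
    200: (111, 264, 108, 140, 896, 163, 196, 135),
    400: (106, 237, 115, 130, 788, 137, 169, 138),
}

# Eosin-pink background and hematoxylin-purple nuclei, 8-bit RGB.
DEFAULT_BACKGROUND = (232, 180, 205)
DEFAULT_NUCLEUS = (110, 70, 160)

# Per-class texture parameter ranges: (density_lo, density_hi) in blobs per
# 1000 px^2, (radius_lo, radius_hi) in px at side=96, (ecc_lo, ecc_hi).
# Ranges are disjoint enough in density that a density threshold separates
# neighbouring classes; "hard" mode shrinks the gaps.
_EASY_TEXTURE = {
    "A": ((0.4, 0.7), (2.5, 3.5), (1.0, 1.3)),
    "F": ((1.2, 1.6), (2.5, 3.5), (1.0, 1.3)),
    "PT": ((2.1, 2.5), (2.5, 3.5), (1.3, 1.8)),
    "TA": ((3.0, 3.4), (2.5, 3.5), (1.0, 1.3)),
    "DC": ((3.9, 4.3), (3.0, 4.5), (1.0, 1.3)),
    "LC": ((4.8, 5.2), (2.0, 3.0), (1.3, 1.8)),
    "MC": ((5.7, 6.1), (3.0, 4.5), (1.0, 1.3)),
    "PC": ((6.6, 7.0), (2.0, 3.0), (1.5, 2.0)),
}

# Per-class background tints (added to the palette background) used in
# color-coded mode; strong enough that a linear classifier on mean RGB
# separates the classes perfectly, which is the construction's contract.
_CLASS_TINTS = {
    "A": (26, -14, -14),
    "F": (-30, 22, -8),
    "PT": (-8, -26, 30),
    "TA": (22, 22, -26),
    "DC": (-26, -22, 22),
    "LC": (30, -4, 22),
    "MC": (-18, 30, 18),
    "PC": (0, -34, -22),
}


@dataclass
class FixtureSpec:
    """Specification of one synthetic dataset.

    Parameters
    ----------
    classes : ordered class labels.
    counts : images per class (same order as ``classes``).
    side : image side length in pixels; must be >= 32.
    background, nucleus : base palette colors (8-bit RGB).
    texture_params : map label -> ((density_lo, hi), (radius_lo, hi),
        (ecc_lo, hi)).  Defaults to well-separated ("easy") ranges.
    color_coded : additionally tint each class's background so classes are
        linearly separable from mean color (the easy training task).
    hard : narrow the inter-class density gaps to induce confusions.
    cast : global RGB shift applied to every image (stain-shift emulation).
    magnification : directory name under which the tree is written.
    seed : master seed; fixes the dataset byte for byte.
    """

    classes: tuple = BREAKHIS_CLASSES
    counts: tuple = (10,) * 8
    side: int = 96
    background: tuple = DEFAULT_BACKGROUND
    nucleus: tuple = DEFAULT_NUCLEUS
    texture_params: dict | None = None
    color_coded: bool = False
    hard: bool = False
    cast: tuple = (0, 0, 0)
    magnification: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.counts = tuple(int(c) for c in self.counts)
        if len(self.counts) != len(self.classes):
            raise ValueError("counts must have one entry per class")
        if any(c <= 0 for c in self.counts):
            raise ValueError("per-class counts must be positive")
        if self.side < 32:
            raise ValueError("side must be at least 32")

    def resolved_texture(self) -> dict:
        if self.texture_params is not None:
            return self.texture_params
        base = {}
        for i, c in enumerate(self.classes):
            key = c if c in _EASY_TEXTURE else BREAKHIS_CLASSES[i % 8]
            (dlo, dhi), rad, ecc = _EASY_TEXTURE[key]
            if self.hard:
                # shrink the density gap between neighbouring classes
                mid = 0.5 * (dlo + dhi)
                dlo, dhi = mid - 0.45, mid + 0.45
            base[c] = ((dlo, dhi), rad, ecc)
        return base

    def to_json(self) -> str:
        d = asdict(self)
        d["texture_params"] = self.resolved_texture()
        return json.dumps(d, indent=2, default=list)


def generate_image(spec: FixtureSpec, cls: str, rng: np.random.Generator) -> np.ndarray:
    """Render one synthetic H&E-like image for class ``cls``.

    Returns an 8-bit RGB array of shape (side, side, 3).
    """
    if cls not in spec.classes:
        raise ValueError(f"unknown class {cls!r}; spec classes are {spec.classes}")
    (dlo, dhi), (rlo, rhi), (elo, ehi) = spec.resolved_texture()[cls]
    side = spec.side
    bg = np.array(spec.background, dtype=np.float64)
    if spec.color_coded:
        bg = bg + np.array(_CLASS_TINTS.get(cls, (0, 0, 0)), dtype=np.float64)
    img = np.ones((side, side, 3)) * bg
    # mild background texture
    img += rng.normal(0.0, 4.0, size=img.shape)

    density = rng.uniform(dlo, dhi)  # blobs per 1000 px^2
    n_blobs = max(1, int(round(density * side * side / 1000.0)))
    scale = side / 96.0
    yy, xx = np.mgrid[0:side, 0:side]
    nucleus = np.array(spec.nucleus, dtype=np.float64)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, side, size=2)
        r = rng.uniform(rlo, rhi) * scale
        ecc = rng.uniform(elo, ehi)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d2 = (u / (r * ecc)) ** 2 + (v / r) ** 2
        alpha = np.clip(1.2 - d2, 0.0, 1.0)[..., None]  # soft-edged ellipse
        tone = nucleus + rng.normal(0.0, 8.0, size=3)
        img = img * (1 - 0.9 * alpha) + tone * 0.9 * alpha
    img = img + np.array(spec.cast, dtype=np.float64)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def apply_stain_shift(image: np.ndarray, cast) -> np.ndarray:
    """Channel-wise affine color shift, clipped to [0, 255].

    Emulates a dataset-level staining cast; ``normalize`` should undo it.
    """
    image = np.asarray(image)
    out = image.astype(np.float64) + np.asarray(cast, dtype=np.float64)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def generate_dataset(spec: FixtureSpec, root, force: bool = False) -> Path:
    """Write a ``magnification/class/*.png`` tree plus a JSON manifest.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns the root path.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(
            f"{root} exists and is not empty; pass force=True to overwrite"
        )
    mag_dir = root / str(spec.magnification)
    rng = np.random.default_rng(spec.seed)
    for cls, count in zip(spec.classes, spec.counts):
        cls_dir = mag_dir / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        # one child generator per class: class content independent of the
        # counts of other classes
        crng = np.random.default_rng([spec.seed, hash_label(cls)])
        for i in range(count):
            img = generate_image(spec, cls, crng)
            Image.fromarray(img).save(cls_dir / f"{cls}_{i:05d}.png")
    (root / "manifest.json").write_text(spec.to_json())
    return root


def hash_label(label: str) -> int:
    """Deterministic small integer from a label (Python's hash() is salted)."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def reference_tile(side: int = 96, seed: int = 12345) -> np.ndarray:
    """A fixed synthetic H&E-like reference image for stain normalization.

    Synthetic stand-in for an expert-selected reference tile; generated,
    not stored, so it is identical everywhere.
    """
    spec = FixtureSpec(classes=("DC",), counts=(1,), side=side, seed=seed)
    rng = np.random.default_rng(seed)
    return generate_image(spec, "DC", rng)
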