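"""Reinhard stain color normalization for H&E histopathology images.

Hematoxylin-and-eosin staining varies between laboratories, scanners and
staining batches; the resulting color shifts are a nuisance covariate for
downstream classifiers.  Reinhard normalization removes first- and
second-order color variation by matching each image's per-channel mean and
standard deviation, computed in the (approximately decorrelated) CIELAB
color space, to those of a reference ("target") image chosen by a
pathologist.

The conversion to and from Lab is pluggable so that variants of the method
(e.g. the original lαβ space) can be substituted; the default is CIELAB
under the D65 illuminant as provided by scikit-image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "LabStats",
    "StainTarget",
    "DegenerateTargetError",
    "rgb_to_lab",
    "lab_to_rgb",
    "compute_lab_stats",
    "fit_target",
    "normalize",
]


class DegenerateTargetError(ValueError):
    """Raised when a reference image has zero variance in some Lab channel."""


# variance below this is numerically indistinguishable from a constant plane
_SIGMA_FLOOR = 1e-6


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image, got shape {image.shape}"
        )
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image has zero-sized dimensions")
    return image


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIELAB (D65).

    Returns a float64 H x W x 3 stack of (L, a, b) planes in the native
    CIELAB ranges (L in [0, 100], a/b roughly [-128, 127]).
    """
    image = _check_rgb(image)
    return _skcolor.rgb2lab(image.astype(np.float64) / 255.0)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Convert a CIELAB image back to 8-bit RGB, clipping out-of-gamut values."""
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 Lab image, got shape {lab.shape}")
    rgb = _skcolor.lab2rgb(lab)  # clips into [0, 1]
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class LabStats:
    """Per-channel mean and population standard deviation in Lab space."""

    mean: np.ndarray  # (mu_L, mu_a, mu_b)
    std: np.ndarray  # (sigma_L, sigma_a, sigma_b), entries >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if self.mean.shape != (3,) or self.std.shape != (3,):
            raise ValueError("LabStats requires 3-vectors for mean and std")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be nonnegative")


def compute_lab_stats(lab: np.ndarray) -> LabStats:
    """Per-plane mean and population (divide-by-N) standard deviation.

    Requires at least two pixels; a single pixel carries no scale
    information and would make the downstream variance transfer undefined.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 Lab image, got shape {lab.shape}")
    if lab.shape[0] * lab.shape[1] < 2:
        raise ValueError("need at least 2 pixels to compute Lab statistics")
    flat = lab.reshape(-1, 3)
    return LabStats(mean=flat.mean(axis=0), std=flat.std(axis=0, ddof=0))


@dataclass(frozen=True)
class StainTarget:
    """Reference color distribution for normalization.

    Carries the Lab statistics of the reference image together with a
    provenance string and the name of the color space used, so a serialized
    target is self-describing.
    """

    stats: LabStats
    provenance: str = "unspecified"
    color_space: str = "CIELAB-D65"

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.stats.mean.tolist(),
                "std": self.stats.std.tolist(),
                "provenance": self.provenance,
                "color_space": self.color_space,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StainTarget":
        obj = json.loads(text)
        return cls(
            stats=LabStats(mean=np.array(obj["mean"]), std=np.array(obj["std"])),
            provenance=obj.get("provenance", "unspecified"),
            color_space=obj.get("color_space", "CIELAB-D65"),
        )


def fit_target(
    target_image: np.ndarray,
    provenance: str = "unspecified",
    rgb_to_lab_fn: Callable[[np.ndarray], np.ndarray] = rgb_to_lab,
) -> StainTarget:
    """Fit a :class:`StainTarget` from a reference RGB image.

    A constant-color reference has zero variance and cannot serve as a
    scaling target; it is rejected here rather than producing a division by
    zero at normalization time.
    """
    stats = compute_lab_stats(rgb_to_lab_fn(_check_rgb(target_image)))
    if np.any(stats.std <= _SIGMA_FLOOR):
        raise DegenerateTargetError(
            "reference image has zero variance in a Lab channel; "
            "choose a reference with color structure"
        )
    return StainTarget(stats=stats, provenance=provenance)


def normalize(
    source: np.ndarray,
    target: StainTarget,
    rgb_to_lab_fn: Callable[[np.ndarray], np.ndarray] = rgb_to_lab,
    lab_to_rgb_fn: Callable[[np.ndarray], np.ndarray] = lab_to_rgb,
) -> np.ndarray:
    """Transfer the target's Lab mean/std onto the source image.

    Each Lab channel C of the source is mapped through
    ``(C - mu_src) * (sigma_tgt / sigma_src) + mu_tgt`` and the result is
    converted back to 8-bit RGB.  A source channel with zero variance
    carries no spread to rescale; for it the sigma-ratio is treated as 1
    (mean shift only) and a warning is emitted.
    """
    lab = rgb_to_lab_fn(_check_rgb(source))
    src = compute_lab_stats(lab)
    ratio = np.empty(3)
    for c in range(3):
        if src.std[c] <= _SIGMA_FLOOR:
            warnings.warn(
                f"source Lab channel {c} has zero variance; applying mean "
                "shift without scaling",
                RuntimeWarning,
                stacklevel=2,
            )
            ratio[c] = 1.0
        else:
            ratio[c] = target.stats.std[c] / src.std[c]
    out = (lab - src.mean) * ratio + target.stats.mean
    return lab_to_rgb_fn(out)
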