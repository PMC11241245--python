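"""Grad-CAM visual explanations.

A class activation heat map is obtained by weighting a convolutional
layer's channels by the spatially pooled gradient of the class score with
respect to that layer, rectifying the weighted sum, upsampling to the
input size and min-max normalizing into [0, 1].  The default target layer
is the CBAM output (the refined 256-channel map), since the attention
block is where the model's spatial focus is formed; any captured layer
can be selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray  # H x W in [0, 1]
    target_class: int
    layer_name: str

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heat map values must lie in [0, 1]")


def grad_cam(model, image: np.ndarray, target_class: int,
             layer: str = "cbam") -> Heatmap:
    """Compute the Grad-CAM heat map of one image for ``target_class``.

    ``image`` is a standardized 3 x side x side array (or side x side x 3,
    transposed automatically).  ``layer`` must be one of the model's
    capturable layers.
    """
    valid = model.grad_cam_layers()
    if layer not in valid:
        raise ValueError(f"unknown layer {layer!r}; valid layers: {valid}")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3 and x.shape[2] == 3 and x.shape[0] != 3:
        x = np.transpose(x, (2, 0, 1))
    if x.ndim != 3:
        raise ValueError(f"expected one 3-channel image, got shape {x.shape}")
    side = x.shape[1]

    capture: dict = {}
    inp = Tensor(x[None], requires_grad=True)
    was_training = model.training
    model.eval()
    try:
        logits = model.forward(inp, capture=capture)
    finally:
        model.train(was_training)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} outside [0, {logits.shape[1]})")
    seed_grad = np.zeros_like(logits.data)
    seed_grad[0, target_class] = 1.0
    logits.backward(seed_grad)

    feat = capture[layer]
    acts = feat.data[0]  # (C, h, w)
    grads = feat.grad[0]
    weights = grads.mean(axis=(1, 2))  # pooled gradient per channel
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = _resize(cam, (side, side), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return Heatmap(values=cam, target_class=int(target_class), layer_name=layer)


def overlay(heatmap: Heatmap, image: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a color-mapped heat map onto an 8-bit RGB image."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps

    image = np.asarray(image)
    if image.shape[:2] != heatmap.values.shape:
        raise ValueError(
            f"size mismatch: image {image.shape[:2]} vs heat map "
            f"{heatmap.values.shape}"
        )
    colored = colormaps[cmap](heatmap.values)[..., :3] * 255.0
    out = (1.0 - alpha) * image.astype(np.float64) + alpha * colored
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def save_panel(panels, path, titles=None) -> None:
    """Write a row of RGB images (e.g. image | heat map | overlay) as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(panels), figsize=(3 * len(panels), 3))
    if len(panels) == 1:
        axes = [axes]
    for i, (ax, panel) in enumerate(zip(axes, panels)):
        ax.imshow(panel)
        ax.axis("off")
        if titles:
            ax.set_title(titles[i], fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
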