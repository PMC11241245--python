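"""Convolutional block attention (CBAM): channel then spatial gating.

Given a feature map F of shape C x H x W, the block computes

    F'  = Mc(F)  * F        (channel attention, Mc of shape C x 1 x 1)
    F'' = Ms(F') * F'       (spatial attention, Ms of shape 1 x H x W)

where Mc = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F))) with a shared
two-layer bottleneck MLP (C -> C/r -> C, reduction ratio r, default 16),
and Ms = sigmoid(conv_kxk([channel-mean; channel-max])) with an odd kernel
(default 7x7) and same-padding.  Both gates lie strictly in (0, 1), so on
nonnegative features the block can only attenuate; the ordering — channel
strictly before spatial — is part of the contract.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


class ChannelAttention(nn.Module):
    """Channel gate: shared bottleneck MLP over avg- and max-pooled descriptors."""

    def __init__(self, channels: int, reduction_ratio: int = 16, rng=None):
        if reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        hidden = max(1, channels // reduction_ratio)
        self.fc1 = nn.Linear(channels, hidden, bias=True, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=True, rng=rng)
        self.channels = channels

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(v)))

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> channel map (N, C, 1, 1), entries in (0, 1)."""
        if not np.all(np.isfinite(x.data)):
            raise ValueError("channel attention requires finite inputs")
        avg = ad.global_avg_pool(x)
        mx = ad.global_max_pool(x)
        logits = self._mlp(avg) + self._mlp(mx)
        gate = ad.sigmoid(logits)
        n, c = gate.shape
        return ad.reshape(gate, (n, c, 1, 1))


class SpatialAttention(nn.Module):
    """Spatial gate: k x k convolution over channel-pooled mean/max planes."""

    def __init__(self, kernel_size: int = 7, rng=None):
        if kernel_size % 2 != 1:
            raise ValueError("spatial attention kernel size must be odd")
        self.conv = nn.Conv2d(2, 1, kernel_size, stride=1,
                              padding=kernel_size // 2, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> spatial map (N, 1, H, W), entries in (0, 1)."""
        avg = ad.reduce_mean(x, axis=1, keepdims=True)
        mx = ad.reduce_max(x, axis=1, keepdims=True)
        pooled = ad.concat([avg, mx], axis=1)
        return ad.sigmoid(self.conv(pooled))


class CBAM(nn.Module):
    """Sequential channel + spatial attention refinement of a feature map."""

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 spatial_kernel: int = 7, rng=None):
        self.channel = ChannelAttention(channels, reduction_ratio, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)
        self.channels = channels

    def attention_maps(self, x: Tensor):
        """Return (Mc, Ms) for inspection; Ms is computed on the
        channel-refined map, as in the sequential formulation."""
        mc = self.channel(x)
        x_ref = ad.mul(x, mc)
        ms = self.spatial(x_ref)
        return mc, ms

    def forward(self, x: Tensor) -> Tensor:
        mc = self.channel(x)
        x = ad.mul(x, mc)  # F'  = Mc(F) * F
        ms = self.spatial(x)
        return ad.mul(x, ms)  # F'' = Ms(F') * F'
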