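"""Assembly of the attention-augmented EfficientNetV2-S classifier.

The network is the EfficientNetV2-S layout — a 3x3/stride-2 stem, three
Fused-MBConv stages (expansion 1/4/4, layers 2/4/4) and three MBConv+SE
stages (expansion 4/6/6, squeeze ratio 0.25, layers 6/9/15) — followed by
one CBAM block on the final 256-channel feature map, a 1x1 convolution to
1280 channels, global average pooling, and a classifier head of two hidden
fully connected layers (width 1024) before the 8-way output.  The stride
product is 32, so a 384x384 input yields a 12x12 final feature map.

Channel counts at width_scale 1 are the reference configuration
(24, 24, 48, 64, 128, 160, 256) for the backbone; ``width_scale`` < 1
shrinks every channel count (rounded to a multiple of 8) for CPU-feasible
tests and is never a paper-configuration setting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .attention import CBAM
from .autodiff import Tensor

# (block kind, expansion, kernel, stride, layers, output channels)
BACKBONE_STAGES = (
    ("fused", 1, 3, 1, 2, 24),
    ("fused", 4, 3, 2, 4, 48),
    ("fused", 4, 3, 2, 4, 64),
    ("mbconv", 4, 3, 2, 6, 128),
    ("mbconv", 6, 3, 1, 9, 160),
    ("mbconv", 6, 3, 2, 15, 256),
)
STEM_CHANNELS = 24
HEAD_CONV_CHANNELS = 1280
SE_RATIO = 0.25
STRIDE_PRODUCT = 32

ABLATION_COMPONENTS = ("cbam", "fc_layers", "stain_norm", "balance_aug", "all_aug")


class ConfigError(ValueError):
    pass


def _round8(c: float) -> int:
    return max(8, int(round(c / 8.0) * 8))


@dataclass(frozen=True)
class ArchitectureConfig:
    num_classes: int = 8
    reduction_ratio: int = 16
    hidden_width: int = 1024
    width_scale: float = 1.0
    input_side: int = 384
    pretrained: bool = False
    dropout: float = 0.2
    spatial_kernel: int = 7
    use_cbam: bool = True
    extra_fc: bool = True

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if not (0.0 < self.width_scale <= 1.0):
            raise ConfigError("width_scale must lie in (0, 1]")
        if self.pretrained and self.width_scale != 1.0:
            raise ConfigError("pretrained weights require width_scale = 1")
        if self.input_side % STRIDE_PRODUCT != 0:
            raise ConfigError(
                f"input_side must be divisible by {STRIDE_PRODUCT} "
                f"(got {self.input_side})"
            )

    def scaled(self, channels: int) -> int:
        if self.width_scale == 1.0:
            return channels
        return _round8(channels * self.width_scale)

    def stage_channels(self) -> tuple:
        chans = [self.scaled(STEM_CHANNELS)]
        chans += [self.scaled(c) for (_, _, _, _, _, c) in BACKBONE_STAGES]
        if self.use_cbam:
            chans.append(chans[-1])  # CBAM preserves the channel count
        chans.append(self.scaled(HEAD_CONV_CHANNELS))
        return tuple(chans)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ModelSummary:
    stage_channels: tuple
    head_widths: tuple
    total_parameters: int
    logits_width: int
    input_side: int
    final_spatial: int


class SqueezeExcite(nn.Module):
    """Channel re-weighting: squeeze (GAP) -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, squeeze: int, rng=None):
        self.fc1 = nn.Linear(channels, squeeze, rng=rng)
        self.fc2 = nn.Linear(squeeze, channels, rng=rng)

    def forward(self, x):
        n, c = x.shape[0], x.shape[1]
        s = ad.global_avg_pool(x)
        s = ad.sigmoid(self.fc2(ad.silu(self.fc1(s))))
        return ad.mul(x, ad.reshape(s, (n, c, 1, 1)))


class FusedMBConv(nn.Module):
    """Fused inverted bottleneck: full 3x3 conv in place of the depthwise."""

    def __init__(self, cin: int, cout: int, expansion: int, stride: int, rng=None):
        self.use_residual = stride == 1 and cin == cout
        hidden = cin * expansion
        if expansion == 1:
            self.expand = nn.Sequential(
                nn.Conv2d(cin, cout, 3, stride, 1, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
                nn.SiLU(),
            )
            self.project = nn.Identity()
        else:
            self.expand = nn.Sequential(
                nn.Conv2d(cin, hidden, 3, stride, 1, bias=False, rng=rng),
                nn.BatchNorm2d(hidden),
                nn.SiLU(),
            )
            self.project = nn.Sequential(
                nn.Conv2d(hidden, cout, 1, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
            )
            if self.use_residual:
                # residual branches start as identity (zero final BN gain),
                # which keeps the deep stack trainable from random init
                self.project.layers[1].gamma.data[...] = 0.0

    def forward(self, x):
        out = self.project(self.expand(x))
        if self.use_residual:
            out = ad.add(out, x)
        return out


class MBConv(nn.Module):
    """Inverted bottleneck with depthwise 3x3 and squeeze-and-excitation."""

    def __init__(self, cin: int, cout: int, expansion: int, stride: int,
                 se_ratio: float = SE_RATIO, rng=None):
        self.use_residual = stride == 1 and cin == cout
        hidden = cin * expansion
        self.expand = nn.Sequential(
            nn.Conv2d(cin, hidden, 1, bias=False, rng=rng),
            nn.BatchNorm2d(hidden),
            nn.SiLU(),
        )
        self.depthwise = nn.Sequential(
            nn.DepthwiseConv2d(hidden, 3, stride, 1, rng=rng),
            nn.BatchNorm2d(hidden),
            nn.SiLU(),
        )
        self.se = SqueezeExcite(hidden, max(1, int(cin * se_ratio)), rng=rng)
        self.project = nn.Sequential(
            nn.Conv2d(hidden, cout, 1, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )
        if self.use_residual:
            self.project.layers[1].gamma.data[...] = 0.0

    def forward(self, x):
        out = self.project(self.se(self.depthwise(self.expand(x))))
        if self.use_residual:
            out = ad.add(out, x)
        return out


def build_backbone(config: ArchitectureConfig, rng=None) -> nn.Sequential:
    """Stem + the six MBConv/Fused-MBConv stages.

    The composition contract (strides, expansions, layer counts, channel
    progression) is fixed; only the channel widths scale.
    """
    if config.pretrained:
        raise ConfigError(
            "no pretrained weight source is available in this build; "
            "set pretrained=False (training starts from random init)"
        )
    rng = rng or np.random.default_rng(0)
    layers: list = [
        nn.Conv2d(3, config.scaled(STEM_CHANNELS), 3, 2, 1, bias=False, rng=rng),
        nn.BatchNorm2d(config.scaled(STEM_CHANNELS)),
        nn.SiLU(),
    ]
    cin = config.scaled(STEM_CHANNELS)
    for kind, expansion, _k, stride, n_layers, cout in BACKBONE_STAGES:
        cout = config.scaled(cout)
        for i in range(n_layers):
            s = stride if i == 0 else 1
            block_cls = FusedMBConv if kind == "fused" else MBConv
            layers.append(block_cls(cin, cout, expansion, s, rng=rng))
            cin = cout
    return nn.Sequential(*layers)


class AttentionEfficientNet(nn.Module):
    """The assembled classifier: backbone -> CBAM -> 1x1 conv -> GAP -> head."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = build_backbone(config, rng=rng)
        feat = config.scaled(BACKBONE_STAGES[-1][-1])
        self.cbam = CBAM(feat, config.reduction_ratio, config.spatial_kernel,
                         rng=rng) if config.use_cbam else nn.Identity()
        head_c = config.scaled(HEAD_CONV_CHANNELS)
        self.head_conv = nn.Sequential(
            nn.Conv2d(feat, head_c, 1, bias=False, rng=rng),
            nn.BatchNorm2d(head_c),
            nn.SiLU(),
        )
        self.drop = nn.Dropout(config.dropout, seed=seed + 1)
        if config.extra_fc:
            hidden = config.scaled(config.hidden_width)
            self.fc = nn.Sequential(
                nn.Linear(head_c, hidden, rng=rng),
                nn.SiLU(),
                nn.Linear(hidden, hidden, rng=rng),
                nn.SiLU(),
                nn.Linear(hidden, config.num_classes, rng=rng),
            )
            self.head_widths = (head_c, hidden, hidden, config.num_classes)
        else:
            self.fc = nn.Sequential(nn.Linear(head_c, config.num_classes, rng=rng))
            self.head_widths = (head_c, config.num_classes)

    def _check_input(self, x) -> None:
        side = self.config.input_side
        if x.data.ndim != 4 or x.shape[1] != 3 or x.shape[2] != side or x.shape[3] != side:
            raise ValueError(
                f"expected a batch of shape N x 3 x {side} x {side}, got {x.shape}"
            )

    def features(self, x, capture: dict | None = None):
        """Run through the convolutional trunk; optionally capture named
        intermediate tensors ('backbone', 'cbam', 'head_conv') for Grad-CAM."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_input(x)
        out = self.backbone(x)
        if capture is not None:
            capture["backbone"] = out
        out = self.cbam(out)
        if capture is not None:
            capture["cbam"] = out
        out = self.head_conv(out)
        if capture is not None:
            capture["head_conv"] = out
        return out

    def forward(self, x, capture: dict | None = None):
        out = self.features(x, capture)
        pooled = ad.global_avg_pool(out)
        return self.fc(self.drop(pooled))

    def predict_proba(self, x) -> np.ndarray:
        with ad.no_grad():
            logits = self.forward(Tensor(np.asarray(x, dtype=np.float32)))
        return ad.softmax(logits.data)

    def summary(self) -> ModelSummary:
        side = self.config.input_side
        return ModelSummary(
            stage_channels=self.config.stage_channels(),
            head_widths=self.head_widths,
            total_parameters=self.num_parameters(),
            logits_width=self.config.num_classes,
            input_side=side,
            final_spatial=side // STRIDE_PRODUCT,
        )

    def grad_cam_layers(self) -> tuple:
        return ("backbone", "cbam", "head_conv")

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.state_dict())
        sidecar = path.with_suffix(".json")
        summary = self.summary()
        sidecar.write_text(json.dumps({
            "architecture": json.loads(self.config.to_json()),
            "summary": {
                "stage_channels": list(summary.stage_channels),
                "head_widths": list(summary.head_widths),
                "total_parameters": summary.total_parameters,
                "logits_width": summary.logits_width,
            },
        }, indent=2))

    @classmethod
    def load(cls, path, seed: int = 0) -> "AttentionEfficientNet":
        path = Path(path)
        sidecar = path.with_suffix(".json")
        config = ArchitectureConfig(**json.loads(sidecar.read_text())["architecture"])
        model = cls(config, seed=seed)
        archive = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        model.load_state_dict({k: archive[k] for k in archive.files})
        return model


def assemble_model(config: ArchitectureConfig, seed: int = 0):
    """Build the classifier and return (model, summary)."""
    model = AttentionEfficientNet(config, seed=seed)
    return model, model.summary()


def ablation_variant(config: ArchitectureConfig, drop: str) -> ArchitectureConfig:
    """Architecture config with exactly one component removed.

    ``cbam`` bypasses the attention block; ``fc_layers`` reduces the head
    to a single fully connected layer.  The pipeline-level components
    (``stain_norm``, ``balance_aug``, ``all_aug``) do not alter the
    architecture; use :func:`ablation_pipeline` for those.
    """
    if drop not in ABLATION_COMPONENTS:
        raise ConfigError(
            f"unknown ablation component {drop!r}; choose from {ABLATION_COMPONENTS}"
        )
    if drop == "cbam":
        return replace(config, use_cbam=False)
    if drop == "fc_layers":
        return replace(config, extra_fc=False)
    return config


def ablation_pipeline(pipeline_config, drop: str):
    """Pipeline config with exactly one preprocessing component removed."""
    from dataclasses import replace as _replace

    if drop not in ABLATION_COMPONENTS:
        raise ConfigError(
            f"unknown ablation component {drop!r}; choose from {ABLATION_COMPONENTS}"
        )
    if drop == "stain_norm":
        return _replace(pipeline_config, use_stain_norm=False)
    if drop == "balance_aug":
        return _replace(pipeline_config, use_balance_aug=False)
    if drop == "all_aug":
        return _replace(pipeline_config, use_balance_aug=False,
                        use_geometric_aug=False)
    return pipeline_config
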