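"""Model/Results facade over the full pipeline.

:class:`TumorClassifier` is constructed from data (a split dataset index
plus architecture/pipeline configuration), mirroring the model-object
convention of statistical modelling packages: ``fit()`` runs the balanced
training loop and returns a :class:`FitResult` that carries the fitted
network, the per-epoch history and a ``summary()``; evaluation and
Grad-CAM explanation hang off the result object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data as data_mod
from . import gradcam as gradcam_mod
from . import metrics as metrics_mod
from .data import (BalancedTrainStream, DatasetIndex, EvalStream,
                   PipelineConfig, index_dataset, plan_balance,
                   stratified_split)
from .model import (ArchitectureConfig, AttentionEfficientNet,
                    ablation_pipeline, ablation_variant, assemble_model)
from .train import TrainingConfig, train


class TumorClassifier:
    """Multi-class tumor sub-type classifier bound to one dataset split."""

    def __init__(self, index: DatasetIndex,
                 arch: ArchitectureConfig | None = None,
                 pipeline: PipelineConfig | None = None,
                 seed: int = 0):
        if not any(r.split for r in index.records):
            raise ValueError(
                "index has no split labels; pass it through stratified_split "
                "or use from_directory()"
            )
        self.index = index
        self.arch = arch or ArchitectureConfig(num_classes=len(index.classes))
        if self.arch.num_classes != len(index.classes):
            raise ValueError(
                f"architecture expects {self.arch.num_classes} classes but the "
                f"index has {len(index.classes)}"
            )
        self.pipeline = pipeline or PipelineConfig(side=self.arch.input_side)
        if self.pipeline.side != self.arch.input_side:
            raise ValueError("pipeline side and architecture input_side differ")
        self.seed = seed
        self.plan = plan_balance(index.subset("train"))

    @classmethod
    def from_directory(cls, root, magnification: int = 40,
                       arch: ArchitectureConfig | None = None,
                       pipeline: PipelineConfig | None = None,
                       classes=None, seed: int = 0,
                       ratios=(0.7, 0.2, 0.1)) -> "TumorClassifier":
        kwargs = {} if classes is None else {"classes": classes}
        index = index_dataset(root, magnification, **kwargs)
        index = stratified_split(index, ratios, seed=seed)
        if arch is None:
            arch = ArchitectureConfig(num_classes=len(index.classes))
        return cls(index, arch, pipeline, seed=seed)

    def ablate(self, drop: str) -> "TumorClassifier":
        """A classifier identical to this one with one component removed."""
        return TumorClassifier(
            self.index,
            ablation_variant(self.arch, drop),
            ablation_pipeline(self.pipeline, drop),
            seed=self.seed,
        )

    def streams(self):
        train_idx = self.index.subset("train")
        return (
            BalancedTrainStream(train_idx, self.plan, self.pipeline, seed=self.seed),
            EvalStream(self.index.subset("val"), self.pipeline),
            EvalStream(self.index.subset("test"), self.pipeline),
        )

    def fit(self, config: TrainingConfig | None = None, out_dir=None,
            verbose: bool = False) -> "FitResult":
        config = config or TrainingConfig(seed=self.seed)
        model, _ = assemble_model(self.arch, seed=config.seed)
        train_stream, val_stream, _ = self.streams()
        model, history = train(model, train_stream, val_stream, config,
                               out_dir=out_dir, verbose=verbose)
        return FitResult(self, model, history, config)


@dataclass
class FitResult:
    """A fitted classifier: weights, training history and evaluation methods."""

    classifier: TumorClassifier
    model: AttentionEfficientNet
    history: object
    training_config: TrainingConfig

    def summary(self) -> str:
        ms = self.model.summary()
        final = self.history.final()
        lines = [
            "Fitted tumor sub-type classifier",
            "=" * 48,
            f"classes: {', '.join(map(str, self.classifier.index.classes))}",
            f"stage channels: {ms.stage_channels}",
            f"head widths: {ms.head_widths}",
            f"parameters: {ms.total_parameters:,}",
            f"input: {ms.input_side}x{ms.input_side} -> "
            f"{ms.final_spatial}x{ms.final_spatial} feature map",
            f"epochs run: {len(self.history)}",
            f"final train loss/acc: {final.train_loss:.4f} / {final.train_acc:.3f}",
            f"final val loss/acc: {final.val_loss:.4f} / {final.val_acc:.3f}",
            f"balanced epoch length: {self.classifier.plan.epoch_length} "
            f"({self.classifier.plan.oversample_target} per class)",
        ]
        return "\n".join(lines)

    def evaluate(self, split: str = "test",
                 batch_size: int | None = None) -> metrics_mod.MetricsReport:
        _, val_stream, test_stream = self.classifier.streams()
        stream = {"val": val_stream, "test": test_stream}[split]
        bs = batch_size or self.training_config.batch_size
        return metrics_mod.evaluate_model(
            self.model, stream, bs,
            metadata={"split": split,
                      "magnification": self.classifier.index.magnification},
        )

    def explain(self, image: np.ndarray, target_class: int,
                layer: str = "cbam") -> gradcam_mod.Heatmap:
        x = data_mod.preprocess(image, self.classifier.pipeline.side,
                                self.classifier.pipeline.effective_target())
        std = data_mod.standardize(x.astype(np.float64) / 255.0,
                                   self.classifier.pipeline.channel_stats)
        return gradcam_mod.grad_cam(self.model, std, target_class, layer)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.model.save(out_dir / "checkpoint.npz")
        self.history.to_csv(out_dir / "history.csv")
        manifest = data_mod.run_manifest(self.classifier.index,
                                         self.classifier.plan,
                                         self.classifier.seed)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
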