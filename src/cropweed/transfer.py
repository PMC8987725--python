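"""Transfer training of a 6-class head with tunable learning-rate factors.

A classifier is a frozen (or slowly fine-tuned) convolutional backbone plus
a freshly initialized fully connected softmax head.  The head's weight and
bias groups each carry a *learning-rate factor* multiplying the base
learning rate; the (weight, bias) factor pair is the 2-d quantity the swarm
optimizers search.  ``fitness_from_factors`` wraps a full train-and-score
round into the scalar the optimizers minimize: one minus test accuracy.

The tested path uses a small random-weight backbone built here; any feature
extractor honoring the same contract (fixed-length deterministic features)
can be plugged in, e.g. an AlexNet-shaped extractor with F=4096 features,
for which the head holds 4096*6 + 6 = 24,582 parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .synthetic import LabeledPatchSet

__all__ = ["ToyBackbone", "TransferHead", "TransferModel", "TrainConfig",
           "build_transfer_model", "train_transfer", "evaluate_accuracy",
           "fitness_from_factors"]


class ToyBackbone:
    """A fixed random conv feature extractor (deterministic in eval mode).

    ``fine_tune_multiplier`` is the small learning-rate multiplier applied
    to backbone weights when fine-tuning is enabled (default path keeps the
    backbone frozen).
    """

    def __init__(
        self,
        in_channels: int = 3,
        side: int = 32,
        feature_dim: int = 32,
        seed: int = 0,
        fine_tune_multiplier: float = 0.1,
    ):
        self.net = nn.build_toy_backbone(in_channels=in_channels, side=side,
                                         feature_dim=feature_dim)
        self.params = self.net.init_params(np.random.default_rng(seed))
        self.feature_dim = feature_dim
        self.in_channels = in_channels
        self.side = side
        self.fine_tune_multiplier = fine_tune_multiplier

    def features(self, patches: np.ndarray) -> np.ndarray:
        """Map (n, side, side, c) patches to (n, feature_dim) features.

        Each feature vector is standardized per sample (zero mean, unit
        variance across its components) so the head's gradient steps are
        well conditioned regardless of the random conv weights' scale.
        """
        x = np.asarray(patches)
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"backbone expects {self.in_channels} channels, got {x.shape[-1]}"
            )
        f = self.net.forward(self.params, x)
        return (f - f.mean(axis=1, keepdims=True)) / (f.std(axis=1, keepdims=True) + 1e-8)


@dataclasses.dataclass
class TransferHead:
    """Fully connected softmax head: weights (F, n_classes), bias (n_classes)."""

    weights: np.ndarray
    bias: np.ndarray
    weight_lr_factor: float
    bias_lr_factor: float

    def __post_init__(self):
        if self.weight_lr_factor <= 0 or self.bias_lr_factor <= 0:
            raise ValueError("learning-rate factors must be > 0")

    @property
    def n_params(self) -> int:
        return self.weights.size + self.bias.size

    def logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(features), axis=-1)


@dataclasses.dataclass
class TransferModel:
    backbone: ToyBackbone
    head: TransferHead

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return self.head.predict(self.backbone.features(patches))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return nn.softmax(self.head.logits(self.backbone.features(patches)))


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Supervised-loop settings.  One "iteration" is one gradient step on one
    mini-batch, matching the small budgets used for optimization-time scoring
    (10) and final training (72/144)."""

    base_lr: float = 0.01
    iterations: int = 10
    batch_size: int = 300  # capped at the training-set size (full batch)
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iteration budget must be >= 0")
        if self.base_lr <= 0 or self.batch_size < 1:
            raise ValueError("invalid base_lr or batch_size")


def build_transfer_model(
    backbone: ToyBackbone,
    n_classes: int = 6,
    factors: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
) -> TransferModel:
    """Attach a freshly initialized head to a backbone.

    The head's effective learning rates are base_lr * weight factor for the
    weight matrix and base_lr * bias factor for the bias vector.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    wf, bf = factors
    rng = np.random.default_rng(seed)
    f = backbone.feature_dim
    head = TransferHead(
        weights=rng.normal(0.0, np.sqrt(2.0 / f), size=(f, n_classes)),
        bias=np.zeros(n_classes),
        weight_lr_factor=float(wf),
        bias_lr_factor=float(bf),
    )
    return TransferModel(backbone=backbone, head=head)


def train_transfer(
    model: TransferModel, trainset: LabeledPatchSet, cfg: TrainConfig
) -> tuple[TransferModel, np.ndarray]:
    """Mini-batch gradient descent on softmax cross-entropy (head only).

    Backbone features are computed once (the backbone is frozen), then each
    iteration draws a mini-batch, takes one head gradient step with the
    per-group effective learning rates, and records the batch loss.  Returns
    the trained model and the loss history (length = iteration budget).
    """
    if len(trainset) == 0:
        raise ValueError("empty training set")
    if trainset.n_channels != model.backbone.in_channels:
        raise ValueError("trainset channels do not match the backbone")
    feats = model.backbone.features(trainset.patches)
    y = trainset.labels
    rng = np.random.default_rng(cfg.seed)
    lr_w = cfg.base_lr * model.head.weight_lr_factor
    lr_b = cfg.base_lr * model.head.bias_lr_factor
    losses = []
    n = len(y)
    for _ in range(cfg.iterations):
        idx = rng.choice(n, size=min(cfg.batch_size, n), replace=False)
        fb, yb = feats[idx], y[idx]
        p = nn.softmax(model.head.logits(fb))
        losses.append(float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-300))))
        dlogits = p
        dlogits[np.arange(len(yb)), yb] -= 1.0
        dlogits /= len(yb)
        model.head.weights -= lr_w * (fb.T @ dlogits)
        model.head.bias -= lr_b * dlogits.sum(axis=0)
    return model, np.asarray(losses)


def evaluate_accuracy(model, testset: LabeledPatchSet) -> float:
    """Fraction of correctly classified test patches.

    ``model`` is anything with a ``predict(patches) -> class indices``
    method (a TransferModel, or any classifier stub in tests).
    """
    if len(testset) == 0:
        raise ValueError("empty test set")
    pred = model.predict(testset.patches)
    return float(np.mean(pred == testset.labels))


def fitness_from_factors(
    factors: tuple[float, float],
    trainset: LabeledPatchSet,
    testset: LabeledPatchSet,
    cfg: TrainConfig,
    backbone: ToyBackbone | None = None,
) -> float:
    """The optimizer's objective: 1 - test accuracy after a short training
    run with the given (weight, bias) learning-rate factor pair.

    Deterministic for fixed factors, datasets, config and backbone: the head
    initialization and batch order derive from ``cfg.seed``.
    """
    if backbone is None:
        backbone = ToyBackbone(in_channels=trainset.n_channels, side=trainset.side)
    model = build_transfer_model(backbone, factors=tuple(factors), seed=cfg.seed)
    model, _ = train_transfer(model, trainset, cfg)
    return 1.0 - evaluate_accuracy(model, testset)
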