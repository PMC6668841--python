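"""Model management: split protocol, architectures, training.

Three classifiers operate on V x 48 timeline images:

* ``standard_cnn`` — an MNIST-style stack (two conv blocks with 2x2
  pooling, dense head). Pooling both axes discards fine temporal order.
* ``rnn`` — a GRU over the 48 hourly column vectors.
* ``cnn_rl`` — conv blocks that pool only the variable axis, preserving all
  48 time steps; the per-time-step convolutional feature vectors feed a GRU
  whose final state drives the output. This combines local pattern
  detection with temporal ordering.

The split protocol is 70% derivation / 30% independent validation, with the
derivation set split 80/20 into training and tuning; early stopping and
model selection use tuning AUC only, and validation ids are asserted never
to enter a training batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .evaluate import roc_auc


@dataclass(frozen=True)
class SplitSpec:
    """Admission-level split: derivation (train + tune) and validation."""

    train_ids: Tuple[str, ...]
    tune_ids: Tuple[str, ...]
    validation_ids: Tuple[str, ...]
    seed: int = 0

    @property
    def derivation_ids(self) -> Tuple[str, ...]:
        return self.train_ids + self.tune_ids

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.tune_ids), set(self.validation_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split sets are not pairwise disjoint")


def make_split(ids: Sequence[str], seed: int) -> SplitSpec:
    """Random 70/30 then 80/20 split (smaller set rounded down)."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 ids to split, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = int(0.3 * len(ids))
    val = [ids[i] for i in perm[:n_val]]
    deriv = [ids[i] for i in perm[n_val:]]
    n_tune = int(0.2 * len(deriv))
    tune = deriv[:n_tune]
    train = deriv[n_tune:]
    return SplitSpec(tuple(train), tuple(tune), tuple(val), seed=seed)


ARCHITECTURES = ("standard_cnn", "rnn", "cnn_rl")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are deliberately desk-scale: small filter counts and a modest
    recurrent width train in seconds per epoch on one CPU while retaining
    the architectural contrasts that matter (pooling away vs preserving the
    time axis).
    """

    architecture: str = "cnn_rl"
    conv_filters: Tuple[int, ...] = (8, 16)
    kernel: int = 3
    recurrent_width: int = 48
    dense_width: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 10
    patience: int = 3
    class_weighting: bool = True
    seed: int = 0

    def validate(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.conv_filters) < 1 or self.recurrent_width < 1 or self.batch_size < 1:
            raise ValueError("sizes must be positive")


class TrainedModel:
    """Classifier handle: predict_proba + final-conv-layer access (Grad-CAM)."""

    def __init__(self, net: nn.Network, config: ModelConfig,
                 image_shape: Tuple[int, int], conv_feature_layer=None):
        self.net = net
        self.config = config
        self.image_shape = image_shape
        self.conv_feature_layer = conv_feature_layer  # post-ReLU of last conv
        self.history: List[Dict] = []
        self.trained = False

    def _check_shape(self, images: np.ndarray):
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != self.image_shape:
            raise ValueError(f"expected images of shape {self.image_shape}, "
                             f"got {images.shape[1:]}")
        return images

    def predict_logit(self, images: np.ndarray, batch: int = 512) -> np.ndarray:
        images = self._check_shape(images)
        out = [self.net.forward(images[i:i + batch], train=False)
               for i in range(0, len(images), batch)]
        return np.concatenate(out)

    def predict_proba(self, images: np.ndarray, batch: int = 512) -> np.ndarray:
        """Per-image probability of in-hospital death, deterministic."""
        return 1.0 / (1.0 + np.exp(-self.predict_logit(images, batch)))

    def conv_activations_and_grads(self, images: np.ndarray):
        """Final-conv feature maps A_k and d(logit)/dA_k per image.

        Gradients flow from the death-class logit back through any
        recurrent/dense head. Raises for architectures without a conv layer.
        """
        if self.conv_feature_layer is None:
            raise ValueError(f"architecture {self.config.architecture!r} has no "
                             f"convolutional layer; Grad-CAM needs one")
        images = self._check_shape(images)
        logits = self.net.forward(images, train=False)
        dA = self.net.backward(np.ones_like(logits), until=self.conv_feature_layer)
        A = self.conv_feature_layer._last_output
        return A, dA


class _RecordingReLU(nn.ReLU):
    """ReLU that keeps its last output (final conv feature maps)."""

    def forward(self, x, train=False):
        y = super().forward(x, train=train)
        self._last_output = y
        return y


def build_model(config: ModelConfig, image_shape: Tuple[int, int]) -> TrainedModel:
    """Build an untrained model for images of ``image_shape = (V, 48)``.

    Identical config + seed gives identical initial parameters.
    """
    config.validate()
    V, T = image_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2166]))
    k = config.kernel
    arch = config.architecture

    if arch == "rnn":
        layers = [
            nn.Transpose12(),
            nn.GRU(V, config.recurrent_width, rng=rng),
            nn.Dropout(config.dropout, rng),
            nn.Dense(config.recurrent_width, 1, rng=rng),
        ]
        net = nn.Network(layers, needs_channel_axis=False)
        return TrainedModel(net, config, image_shape, conv_feature_layer=None)

    filters = list(config.conv_filters)

    if arch == "standard_cnn":
        layers = []
        cin, Vc, Tc = 1, V, T
        conv_relu = None
        for i, f in enumerate(filters):
            conv_relu = _RecordingReLU()
            layers += [nn.Conv2d(cin, f, k, rng=rng), conv_relu, nn.MaxPool2d(2, 2)]
            cin, Vc, Tc = f, Vc // 2, Tc // 2
            if Vc < 1 or Tc < 1:
                raise ValueError(f"image shape {image_shape} too small for "
                                 f"{len(filters)} 2x2 poolings (block {i + 1} "
                                 f"leaves {Vc}x{Tc})")
        layers += [
            nn.Flatten(),
            nn.Dense(cin * Vc * Tc, config.dense_width, rng=rng), nn.ReLU(),
            nn.Dropout(config.dropout, rng),
            nn.Dense(config.dense_width, 1, rng=rng),
        ]
        return TrainedModel(nn.Network(layers), config, image_shape,
                            conv_feature_layer=conv_relu)

    # cnn_rl: pool only the variable axis, keep all T time steps
    layers = []
    cin, Vc = 1, V
    conv_relu = None
    for i, f in enumerate(filters):
        conv_relu = _RecordingReLU()
        layers += [nn.Conv2d(cin, f, k, rng=rng), conv_relu, nn.MaxPool2d(2, 1)]
        cin, Vc = f, Vc // 2
        if Vc < 1:
            raise ValueError(f"image shape {image_shape} too small for "
                             f"{len(filters)} 2x1 poolings on the variable axis "
                             f"(block {i + 1} leaves {Vc})")
    layers += [
        nn.TimeFlatten(),
        nn.GRU(cin * Vc, config.recurrent_width, rng=rng, output="mean"),
        nn.Dropout(config.dropout, rng),
        nn.Dense(config.recurrent_width, 1, rng=rng),
    ]
    return TrainedModel(nn.Network(layers), config, image_shape,
                        conv_feature_layer=conv_relu)


def train_model(model: TrainedModel, images: np.ndarray, labels: np.ndarray,
                ids: Sequence[str], split: SplitSpec,
                config: Optional[ModelConfig] = None) -> TrainedModel:
    """Train with class-weighted BCE and early stopping on tuning AUC.

    ``images``/``labels``/``ids`` are aligned arrays covering at least the
    derivation split. Validation ids are never placed in a batch (asserted).
    Returns the model with best-tuning-epoch parameters and a history of
    per-epoch loss / tuning AUC.
    """
    config = config or model.config
    idx = {a: i for i, a in enumerate(ids)}
    train_idx = np.array([idx[a] for a in split.train_ids if a in idx])
    tune_idx = np.array([idx[a] for a in split.tune_ids if a in idx])
    if len(train_idx) == 0 or len(tune_idx) == 0:
        raise ValueError("train/tune split not represented in the provided ids")
    forbidden = set(split.validation_ids)
    assert not (set(np.asarray(ids)[train_idx]) | set(np.asarray(ids)[tune_idx])) & forbidden, \
        "validation admissions leaked into a training/tuning set"

    y_train = labels[train_idx].astype(np.float64)
    if y_train.min() == y_train.max():
        raise ValueError("training labels are single-class; cannot fit a classifier")
    x_train = images[train_idx].astype(np.float32)
    x_tune = images[tune_idx].astype(np.float32)
    y_tune = labels[tune_idx]

    if config.class_weighting:
        n_pos = y_train.sum()
        w_pos = len(y_train) / (2.0 * n_pos)
        w_neg = len(y_train) / (2.0 * (len(y_train) - n_pos))
    else:
        w_pos = w_neg = 1.0
    sample_w = np.where(y_train == 1, w_pos, w_neg)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7411]))
    opt = nn.Adam(model.net, lr=config.learning_rate)
    best_auc, best_weights, best_epoch, since_best = -np.inf, None, -1, 0
    model.history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            b = order[i:i + config.batch_size]
            logits = model.net.forward(x_train[b], train=True)
            loss, dlogit = nn.weighted_bce_with_logits(logits, y_train[b], sample_w[b])
            model.net.backward(dlogit)
            opt.step()
            losses.append(loss)
        tune_scores = model.predict_logit(x_tune)
        tune_auc = roc_auc(y_tune, tune_scores)
        model.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                              "tune_auc": float(tune_auc)})
        if tune_auc > best_auc:
            best_auc, best_weights, best_epoch = tune_auc, model.net.get_weights(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_weights is not None:
        model.net.set_weights(best_weights)
    model.best_epoch = best_epoch
    model.trained = True
    return model


def predict_proba(model: TrainedModel, images: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper around the model method."""
    return model.predict_proba(images)
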