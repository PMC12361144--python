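"""Model training: unimodal backbones and the final multimodal model.

Covers the class-weighted cross-entropy used everywhere (class weights
w_c = N / (|C| * N_c), so rare classes are up-weighted and
sum_c N_c * w_c = N), the per-organ image augmentations, the exponentially
decaying learning rate, multimodal dropout (zeroing whole modalities during
training to induce robustness to missing organs), and the two training loops:

* ``train_unimodal`` — trains one organ's backbone with early stopping on
  validation loss (optionally a frozen-base phase followed by fine-tuning);
* ``train_multimodal`` — trains a fusion model on cached feature batches,
  shuffled each epoch in buffers of 12, with optional multimodal dropout,
  early stopping on validation macro F1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import f1_macro
from .synthetic import ORGANS


# ---------------------------------------------------------------------------
# loss and class weights
# ---------------------------------------------------------------------------

@dataclass
class ClassWeights:
    weights: np.ndarray  # w_c indexed by contiguous class id
    n_total: int
    counts: np.ndarray

    def per_sample(self, labels: np.ndarray) -> np.ndarray:
        return self.weights[np.asarray(labels)]


def compute_class_weights(counts: np.ndarray | list[int]) -> ClassWeights:
    """w_c = N / (|C| * N_c); satisfies sum_c N_c * w_c = N exactly."""
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 1):
        raise ValueError("every class must have at least one training instance")
    n = int(counts.sum())
    weights = n / (len(counts) * counts.astype(np.float64))
    return ClassWeights(weights, n, counts)


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray | None = None,
                           eps: float = 1e-7) -> float:
    """Mean over the batch of -w_{y_i} * log(p_{i, y_i}).

    With unit weights this is the plain mean cross-entropy.  Probabilities at
    the true class are clipped below at ``eps``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    p_true = np.clip(probs[np.arange(len(labels)), labels], eps, 1.0)
    w = np.ones(len(labels)) if weights is None else np.asarray(weights)[labels]
    return float(-(w * np.log(p_true)).mean())


def _ce_grad_logits(probs: np.ndarray, labels: np.ndarray,
                    sample_weights: np.ndarray) -> np.ndarray:
    """Gradient of the weighted CE w.r.t. pre-softmax logits."""
    g = probs.copy()
    g[np.arange(len(labels)), labels] -= 1.0
    return g * sample_weights[:, None] / len(labels)


# ---------------------------------------------------------------------------
# augmentations and multimodal dropout
# ---------------------------------------------------------------------------

@dataclass
class AugmentationSpec:
    contrast: bool = False
    horizontal_flip: bool = True
    vertical_flip: bool = False
    contrast_range: tuple[float, float] = (0.75, 1.25)
    apply_prob: float = 0.5


#: per-organ augmentations: contrast helps colour-dominated organs, flips are
#: safe for all; vertical flip only where orientation is uninformative
DEFAULT_AUGMENTATIONS = {
    "flower": AugmentationSpec(contrast=True, horizontal_flip=True, vertical_flip=False),
    "leaf": AugmentationSpec(contrast=False, horizontal_flip=True, vertical_flip=True),
    "fruit": AugmentationSpec(contrast=True, horizontal_flip=True, vertical_flip=False),
    "stem": AugmentationSpec(contrast=False, horizontal_flip=True, vertical_flip=False),
}


def contrast_augment(image: np.ndarray, k: float) -> np.ndarray:
    """Scale contrast about each channel's mean: (c - mu) * k + mu, clipped.

    The per-channel mean is preserved exactly before clipping; k = 1 is the
    identity and k = 0 collapses each channel to its mean.
    """
    if k <= 0 and k != 0:
        raise ValueError("contrast factor k must be >= 0")
    mu = image.mean(axis=(0, 1), keepdims=True)
    lo, hi = (-1.0, 1.0) if image.min() < 0 else (0.0, 1.0)
    return np.clip((image - mu) * k + mu, lo, hi)


def apply_augmentations(image: np.ndarray, spec: AugmentationSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Apply each enabled augmentation independently with probability 0.5."""
    if spec.contrast and rng.random() < spec.apply_prob:
        image = contrast_augment(image, rng.uniform(*spec.contrast_range))
    if spec.horizontal_flip and rng.random() < spec.apply_prob:
        image = image[:, ::-1, :]
    if spec.vertical_flip and rng.random() < spec.apply_prob:
        image = image[::-1, :, :]
    return image


@dataclass
class MultimodalDropoutSpec:
    """Per-modality probability of zeroing an organ image during training."""

    rate: float = 0.125

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("multimodal dropout rate must be in [0, 1]")


def multimodal_dropout(modality_images: dict[str, np.ndarray],
                       spec: MultimodalDropoutSpec,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Independently zero each present modality with probability ``spec.rate``.

    Modalities may all be dropped in one sample (independent draws); the
    label and absent modalities are untouched.
    """
    out = {}
    for organ, img in modality_images.items():
        if rng.random() < spec.rate:
            out[organ] = np.zeros_like(img)
        else:
            out[organ] = img
    return out


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def exponential_lr(step: int, initial: float, decay_rate: float = 0.95,
                   decay_steps: int = 200, staircase: bool = False) -> float:
    """lr(step) = initial * decay_rate ** (step / decay_steps).

    Continuous exponent by default (reaches ``decay_rate`` of its value every
    ``decay_steps`` steps exactly); ``staircase`` floors the exponent.
    """
    if not 0.0 < decay_rate <= 1.0 or decay_steps < 1:
        raise ValueError("decay_rate must be in (0,1] and decay_steps >= 1")
    exponent = step / decay_steps
    if staircase:
        exponent = np.floor(exponent)
    return float(initial * decay_rate ** exponent)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class TinyCNNBackbone:
    """A 3-block CNN declaring 4 fusible layers.

    Blocks of stride-2 valid 3x3 convolutions with ReLU, global average
    pooling, an intermediate dense layer with batch normalisation and ReLU,
    and a softmax classifier.  The fusible layers exposed for fusion are, from
    shallow to deep: the pooled outputs of the three conv blocks and the
    intermediate dense activation.
    """

    def __init__(self, modality: str, n_classes: int, seed: int,
                 widths: tuple[int, int, int] = (8, 16, 32),
                 intermediate: int = 32, dropout: float = 0.0,
                 l1: float = 0.0, l2: float = 0.0):
        rng = np.random.default_rng(seed)
        self.modality = modality
        self.n_classes = n_classes
        self.widths = widths
        self.intermediate_width = intermediate
        self.conv = [nn.Conv2d(3, widths[0], rng),
                     nn.Conv2d(widths[0], widths[1], rng),
                     nn.Conv2d(widths[1], widths[2], rng)]
        self.acts = [nn.relu() for _ in range(3)]
        self.gap = nn.GlobalAvgPool()
        self.inter = nn.Dense(widths[2], intermediate, rng)
        self.bn = nn.BatchNorm(intermediate)
        self.inter_act = nn.relu()
        self.drop = nn.Dropout(dropout, np.random.default_rng(rng.integers(2 ** 31)))
        self.clf = nn.Dense(intermediate, n_classes, rng, l1=l1, l2=l2)

    # -- fusion interface ----------------------------------------------------
    @property
    def fusible_layers(self) -> list[tuple[str, int]]:
        """Ordered (name, width) pairs exposed for fusion, shallow to deep."""
        return [("block1", self.widths[0]), ("block2", self.widths[1]),
                ("block3", self.widths[2]),
                ("intermediate", self.intermediate_width)]

    @property
    def n_fusible(self) -> int:
        return len(self.fusible_layers)

    def fusible_features(self, x: np.ndarray) -> list[np.ndarray]:
        """Pooled per-layer feature vectors for a batch of images (inference)."""
        feats = []
        h = x
        for conv, act in zip(self.conv, self.acts):
            h = act(conv.forward(h))
            feats.append(h.mean(axis=(1, 2)))
        pooled = h.mean(axis=(1, 2))
        z = self.inter_act(self.bn.forward(self.inter.forward(pooled)))
        feats.append(z)
        return feats

    # -- classification path --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for conv, act in zip(self.conv, self.acts):
            h = act.forward(conv.forward(h, train))
        h = self.gap.forward(h)
        h = self.inter_act.forward(self.bn.forward(self.inter.forward(h, train), train))
        h = self.drop.forward(h, train)
        self._logits = self.clf.forward(h, train)
        return nn.softmax(self._logits)

    def backward(self, dlogits: np.ndarray, train_base: bool = True) -> None:
        d = self.clf.backward(dlogits)
        d = self.drop.backward(d)
        d = self.inter.backward(self.bn.backward(self.inter_act.backward(d)))
        if not train_base:
            return
        d = self.gap.backward(d)
        for conv, act in zip(reversed(self.conv), reversed(self.acts)):
            d = conv.backward(act.backward(d))

    def base_params(self) -> list[nn.Param]:
        return [p for c in self.conv for p in c.params()]

    def appended_params(self) -> list[nn.Param]:
        return self.inter.params() + self.bn.params() + self.clf.params()

    def penalty(self) -> float:
        return self.clf.penalty()

    def get_weights(self) -> list[np.ndarray]:
        ps = self.base_params() + self.appended_params()
        return [p.value.copy() for p in ps] + [self.bn.run_mean.copy(),
                                               self.bn.run_var.copy()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.base_params() + self.appended_params()
        for p, w in zip(ps, weights[:len(ps)]):
            p.value[...] = w
        self.bn.run_mean[...] = weights[-2]
        self.bn.run_var[...] = weights[-1]


# ---------------------------------------------------------------------------
# training specs and loops
# ---------------------------------------------------------------------------

@dataclass
class TrainSpec:
    """Hyperparameters of one training run (unimodal or multimodal)."""

    optimizer: str = "adam"
    initial_lr: float = 1e-3
    decay_rate: float = 0.95
    decay_steps: int = 200
    batch_size: int = 32
    epochs: int = 40
    es_patience: int = 10
    es_start_epoch: int = 0
    l1: float = 0.0
    l2: float = 0.0
    dropout: float = 0.0
    intermediate_width: int = 32
    train_base: bool = True      # False = transfer-learning frozen phase
    fine_tune: bool = False      # optional second phase unfreezing the base
    fine_tune_lr: float = 1e-4
    fine_tune_epochs: int = 40
    fine_tune_es_start: int = 0
    staircase: bool = False

    def __post_init__(self):
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.decay_rate <= 1.0:
            raise ValueError("decay_rate must be in (0, 1]")


def _train_phase(model: TinyCNNBackbone, data, spec: TrainSpec, params,
                 train_base: bool, lr0: float, epochs: int, es_start: int,
                 rng: np.random.Generator, augment: AugmentationSpec | None,
                 class_weights: ClassWeights, history: list[dict]) -> None:
    x_train, y_train, x_val, y_val = data
    opt = nn.Adam(params, lr=lr0)
    n = len(y_train)
    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            xb = x_train[idx]
            if augment is not None:
                xb = np.stack([apply_augmentations(img, augment, rng)
                               for img in xb])
            probs = model.forward(xb, train=True)
            yb = y_train[idx]
            losses.append(weighted_cross_entropy(probs, yb, class_weights.weights)
                          + model.penalty())
            opt.zero_grad()
            model.backward(_ce_grad_logits(probs, yb, class_weights.per_sample(yb)),
                           train_base=train_base)
            opt.step(exponential_lr(step, lr0, spec.decay_rate, spec.decay_steps,
                                    spec.staircase))
            step += 1
        val_probs = model.forward(x_val, train=False)
        val_loss = weighted_cross_entropy(val_probs, y_val, class_weights.weights)
        val_f1 = f1_macro(np.argmax(val_probs, axis=1), y_val,
                          n_classes=model.n_classes)
        history.append({"epoch": len(history), "loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_f1_macro": val_f1})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
        if epoch >= es_start and epoch - max(best_epoch, 0) >= spec.es_patience:
            break
    model.set_weights(best_weights)


def train_unimodal(model: TinyCNNBackbone, x_train, y_train, x_val, y_val,
                   spec: TrainSpec, seed: int = 0,
                   augment: AugmentationSpec | None = None) -> list[dict]:
    """Train one organ's model; returns the per-epoch history.

    Phase 1 trains the appended intermediate/classifier layers (and the base
    if ``spec.train_base``); early stopping monitors validation loss and the
    best weights are restored.  If ``spec.fine_tune``, a second phase
    unfreezes the base with a lower learning rate and early stopping
    suppressed before ``spec.fine_tune_es_start``.
    """
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(seed)
    counts = np.bincount(y_train, minlength=model.n_classes)
    cw = compute_class_weights(np.maximum(counts, 1))
    data = (x_train, y_train, x_val, y_val)
    history: list[dict] = []
    params = model.appended_params() + (model.base_params() if spec.train_base else [])
    _train_phase(model, data, spec, params, spec.train_base, spec.initial_lr,
                 spec.epochs, 0, rng, augment, cw, history)
    if spec.fine_tune:
        params = model.appended_params() + model.base_params()
        _train_phase(model, data, spec, params, True, spec.fine_tune_lr,
                     spec.fine_tune_epochs, spec.fine_tune_es_start, rng,
                     augment, cw, history)
    return history


# ---------------------------------------------------------------------------
# multimodal training on cached features
# ---------------------------------------------------------------------------

def _shuffle_in_buffers(n_batches: int, buffer: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Permute batch indices within consecutive windows of ``buffer`` batches."""
    order = np.arange(n_batches)
    for start in range(0, n_batches, buffer):
        window = order[start:start + buffer]
        order[start:start + buffer] = window[rng.permutation(len(window))]
    return order


def train_multimodal(model, train_feats, y_train, val_feats, y_val,
                     spec: TrainSpec, md_spec: MultimodalDropoutSpec | None = None,
                     seed: int = 0, buffer_size: int = 12) -> list[dict]:
    """Train a fusion model on cached per-modality feature batches.

    ``train_feats``/``val_feats`` map modality -> list of per-fusible-layer
    arrays of shape (n_records, dim); records missing a modality already carry
    that backbone's zero-image features.  Batches are partitioned once and
    shuffled each epoch within buffers of ``buffer_size``; multimodal dropout
    replaces a sampled modality's features with the zero-image features.
    Early stopping monitors validation macro F1 and restores the best weights.
    """
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("empty training or validation split")
    ss = np.random.SeedSequence(seed)
    batch_rng, md_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    counts = np.bincount(y_train, minlength=model.n_classes)
    cw = compute_class_weights(np.maximum(counts, 1))

    n = len(y_train)
    batch_bounds = [(s, min(s + spec.batch_size, n))
                    for s in range(0, n, spec.batch_size)]
    batches = []
    for lo, hi in batch_bounds:
        feats = {m: [layer[lo:hi] for layer in layers]
                 for m, layers in train_feats.items()}
        batches.append((feats, y_train[lo:hi]))

    opt = nn.Adam(model.params(), lr=spec.initial_lr)
    best_f1 = -np.inf
    best_weights = model.get_weights()
    best_epoch = -1
    history: list[dict] = []
    step = 0
    for epoch in range(spec.epochs):
        order = _shuffle_in_buffers(len(batches), buffer_size, batch_rng)
        losses = []
        for b in order:
            feats, yb = batches[b]
            if md_spec is not None and md_spec.rate > 0:
                feats = {m: [layer.copy() for layer in layers]
                         for m, layers in feats.items()}
                for m in feats:
                    drop = md_rng.random(len(yb)) < md_spec.rate
                    if drop.any():
                        zf = model.zero_features[m]
                        for li, layer in enumerate(feats[m]):
                            layer[drop] = zf[li]
            probs = model.forward(feats, train=True)
            losses.append(weighted_cross_entropy(probs, yb, cw.weights))
            opt.zero_grad()
            model.backward(_ce_grad_logits(probs, yb, cw.per_sample(yb)))
            opt.step(exponential_lr(step, spec.initial_lr, spec.decay_rate,
                                    spec.decay_steps, spec.staircase))
            step += 1
        val_probs = model.forward(val_feats, train=False)
        val_loss = weighted_cross_entropy(val_probs, y_val, cw.weights)
        val_f1 = f1_macro(np.argmax(val_probs, axis=1), y_val,
                          n_classes=model.n_classes)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_f1_macro": val_f1})
        if val_f1 > best_f1 + 1e-12:
            best_f1 = val_f1
            best_weights = model.get_weights()
            best_epoch = epoch
        if epoch >= spec.es_start_epoch and epoch - max(best_epoch, 0) >= spec.es_patience:
            break
    model.set_weights(best_weights)
    return history
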