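"""Multimodal fusion architecture search (MFAS) over frozen unimodal backbones.

A fusion configuration is a short sequence of tuples
``gamma_l = (gamma_l^1, ..., gamma_l^m, gamma_l^a)``: for fusion layer ``l``,
which fusible layer of each modality's backbone to tap and which activation to
use.  Layer ``l`` concatenates the selected (globally average-pooled) features
— plus the previous fusion layer's output when ``l > 1`` — into a dense layer,
and the last fusion layer feeds a softmax classifier.  Only fusion and
classifier weights train; backbones stay frozen, so per-record backbone
features are extracted once and cached.

The search is progressive and surrogate-guided: the single-layer level is
enumerated exhaustively, then each (iteration, level) step extends or replaces
the ``l``-th layer of the sampled set, ranks candidates with an LSTM sequence
regressor trained on all results so far, and draws the next sampled set by
temperature sampling with an inverse-exponential temperature schedule.
Weights of fusion layers are shared across configurations through a store
keyed by (layer position, weight shape, activation); revisited configurations
retain their best score.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluation import f1_macro
from .training import (_ce_grad_logits, _shuffle_in_buffers,
                       compute_class_weights, weighted_cross_entropy)

logger = logging.getLogger(__name__)

DEFAULT_ACTIVATIONS = ("relu", "sigmoid")
TEMPERATURE_DEFAULTS = {"t_max": 10.0, "t_min": 0.2, "d": 4.0}


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionLayerSpec:
    """One fusion layer: per-modality fusible-layer indices + activation index.

    All indices are 1-based; ``gamma[:-1]`` index each modality's fusible
    layers (shallow to deep), ``gamma[-1]`` indexes the activation list.
    """

    gamma: tuple[int, ...]

    @property
    def modality_indices(self) -> tuple[int, ...]:
        return self.gamma[:-1]

    @property
    def activation_index(self) -> int:
        return self.gamma[-1]


@dataclass(frozen=True)
class FusionConfig:
    layers: tuple[FusionLayerSpec, ...]

    def __post_init__(self):
        if not self.layers:
            raise ValueError("a fusion configuration needs at least one layer")

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class CandidateResult:
    config: FusionConfig
    score: float
    epochs_trained: int


def validate_config(config: FusionConfig, ns: tuple[int, ...], k: int) -> None:
    for spec in config.layers:
        if len(spec.gamma) != len(ns) + 1:
            raise ValueError("layer tuple arity does not match modality count")
        for i, (g, n) in enumerate(zip(spec.modality_indices, ns)):
            if not 1 <= g <= n:
                raise ValueError(f"fusible-layer index {g} out of range for "
                                 f"modality {i} (1..{n})")
        if not 1 <= spec.activation_index <= k:
            raise ValueError(f"activation index {spec.activation_index} out of"
                             f" range (1..{k})")


# ---------------------------------------------------------------------------
# search-space arithmetic
# ---------------------------------------------------------------------------

def enumerate_single_layer_configs(ns: tuple[int, ...], k: int) -> list[FusionLayerSpec]:
    """All (prod_i n_i) * k single fusion-layer tuples, in deterministic order."""
    if not ns:
        raise ValueError("need at least one modality")
    if any(n < 1 for n in ns) or k < 1:
        raise ValueError("layer and activation counts must be >= 1")
    ranges = [range(1, n + 1) for n in ns] + [range(1, k + 1)]
    return [FusionLayerSpec(g) for g in itertools.product(*ranges)]


def search_space_size(L: int, ns: tuple[int, ...], k: int) -> int:
    """((n_1 * ... * n_m) * k) ** L, exact arbitrary-precision integer."""
    if L < 1:
        raise ValueError("L must be >= 1")
    per_layer = k
    for n in ns:
        per_layer *= n
    return per_layer ** L


def count_schedule(initial_count: int, iterations: int, levels: int,
                   n_sampled: int, epochs_per_candidate: int,
                   parallel_batches: int = 1) -> dict[str, float]:
    """Search cost accounting.

    The first level enumerates ``initial_count`` architectures (optionally in
    ``parallel_batches`` concurrent groups); each of the remaining
    ``iterations * levels - 1`` steps samples ``n_sampled`` more.
    """
    if min(initial_count, iterations, levels, n_sampled,
           epochs_per_candidate, parallel_batches) < 1:
        raise ValueError("all schedule counts must be >= 1")
    remaining = iterations * levels - 1
    max_unique = initial_count + n_sampled * remaining
    per_worker = (initial_count / parallel_batches
                  + n_sampled * remaining) * epochs_per_candidate
    return {
        "max_unique_architectures": max_unique,
        "per_worker_epochs": per_worker,
        "sequential_epochs": max_unique * epochs_per_candidate,
    }


# ---------------------------------------------------------------------------
# token encoding for the surrogate
# ---------------------------------------------------------------------------

def vocab_size(ns: tuple[int, ...], k: int) -> int:
    return 1 + sum(ns) + k


def encode_config(config: FusionConfig, ns: tuple[int, ...], k: int,
                  L: int) -> np.ndarray:
    """Injective token sequence; 0 is padding, real tokens are >= 1.

    Per layer, one token per modality (offset by the preceding modalities'
    fusible-layer counts) plus one activation token; right zero-padded to
    ``L * (m + 1)`` tokens.
    """
    offsets = np.concatenate([[0], np.cumsum(ns)])
    tokens = []
    for spec in config.layers:
        for i, g in enumerate(spec.modality_indices):
            tokens.append(1 + offsets[i] + (g - 1))
        tokens.append(1 + offsets[-1] + (spec.activation_index - 1))
    out = np.zeros(L * (len(ns) + 1), dtype=np.intp)
    out[:len(tokens)] = tokens
    return out


def decode_config(tokens: np.ndarray, ns: tuple[int, ...], k: int) -> FusionConfig:
    offsets = np.concatenate([[0], np.cumsum(ns)])
    m = len(ns)
    tokens = [int(t) for t in tokens if t > 0]
    if len(tokens) % (m + 1) != 0:
        raise ValueError("token sequence length is not a multiple of m + 1")
    layers = []
    for start in range(0, len(tokens), m + 1):
        chunk = tokens[start:start + m + 1]
        gamma = tuple(chunk[i] - 1 - offsets[i] + 1 for i in range(m))
        gamma += (chunk[m] - 1 - offsets[-1] + 1,)
        layers.append(FusionLayerSpec(gamma))
    return FusionConfig(tuple(layers))


# ---------------------------------------------------------------------------
# surrogate
# ---------------------------------------------------------------------------

def surrogate_fit(results: dict[FusionConfig, float], ns: tuple[int, ...],
                  k: int, L: int, seed: int,
                  surrogate: nn.LSTMRegressor | None = None,
                  epochs: int = 50, batch_size: int = 64) -> nn.LSTMRegressor:
    """(Re)fit the sequence regressor on the entire result set."""
    if not results:
        raise ValueError("surrogate fitting needs at least one scored config")
    if surrogate is None:
        surrogate = nn.LSTMRegressor(vocab_size(ns, k), seed=seed)
    tokens = np.stack([encode_config(c, ns, k, L) for c in results])
    scores = np.array(list(results.values()))
    surrogate.fit(tokens, scores, epochs=epochs, batch_size=batch_size)
    return surrogate


def surrogate_score(surrogate: nn.LSTMRegressor, configs: list[FusionConfig],
                    ns: tuple[int, ...], k: int, L: int) -> np.ndarray:
    tokens = np.stack([encode_config(c, ns, k, L) for c in configs])
    return surrogate.predict(tokens)


# ---------------------------------------------------------------------------
# temperature sampling
# ---------------------------------------------------------------------------

def temperature_at_step(s: int, t_max: float = TEMPERATURE_DEFAULTS["t_max"],
                        t_min: float = TEMPERATURE_DEFAULTS["t_min"],
                        d: float = TEMPERATURE_DEFAULTS["d"]) -> float:
    """(t_max - t_min) * exp(-(s/d)^2) + t_min: t_max at s=0, decays to t_min."""
    if not (t_max >= t_min > 0 and d > 0):
        raise ValueError("require t_max >= t_min > 0 and d > 0")
    return float((t_max - t_min) * np.exp(-((s / d) ** 2)) + t_min)


def sample_with_temperature(scores: np.ndarray, t: float, count: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample ``count`` distinct indices with per-draw weights p_i^(1/t).

    p_i = a_i / sum_j a_j; higher temperature flattens the distribution.
    All-zero scores fall back to uniform sampling with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if np.any(scores < 0):
        raise ValueError("scores must be nonnegative")
    if count > len(scores):
        raise ValueError("cannot sample more configs than available")
    total = scores.sum()
    if total <= 0:
        logger.warning("all candidate scores are zero; sampling uniformly")
        return rng.choice(len(scores), size=count, replace=False)
    p = scores / total
    # sequential draws without replacement, renormalising p^(1/t) each time
    logw = np.full(len(p), -np.inf)
    pos = p > 0
    logw[pos] = np.log(p[pos]) / t
    chosen = []
    available = np.ones(len(p), dtype=bool)
    for _ in range(count):
        w = np.exp(logw - logw[available].max())
        w[~available] = 0.0
        if w.sum() <= 0:  # remaining scores were zero -> uniform among them
            w = available.astype(float)
        w /= w.sum()
        j = int(rng.choice(len(p), p=w))
        chosen.append(j)
        available[j] = False
        logw[j] = -np.inf
    return np.array(chosen, dtype=int)


# ---------------------------------------------------------------------------
# weight sharing
# ---------------------------------------------------------------------------

def shared_weight_key(layer_position: int, weight_shape: tuple[int, ...],
                      activation_index: int) -> tuple:
    """Fusion-layer weights are shared iff position, shape AND activation match."""
    return (int(layer_position), tuple(int(s) for s in weight_shape),
            int(activation_index))


class SharedWeightStore:
    """Map from shared-weight keys to (W, b) arrays, shared across configs."""

    def __init__(self):
        self._store: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def __contains__(self, key) -> bool:
        return key in self._store

    def __len__(self) -> int:
        return len(self._store)

    def get(self, key):
        return self._store.get(key)

    def put(self, key, W: np.ndarray, b: np.ndarray) -> None:
        self._store[key] = (W.copy(), b.copy())


# ---------------------------------------------------------------------------
# fusion network
# ---------------------------------------------------------------------------

class FusionModel:
    """Trainable fusion head over frozen per-modality feature caches.

    ``forward`` consumes a dict modality -> list of per-fusible-layer feature
    arrays of shape (batch, dim); backbone weights are never touched, so
    gradients stop at the feature inputs.
    """

    def __init__(self, modalities: list[str], feature_dims: dict[str, list[int]],
                 config: FusionConfig, fusion_width: int | list[int],
                 n_classes: int, rng: np.random.Generator,
                 store: SharedWeightStore | None = None,
                 activations: tuple[str, ...] = DEFAULT_ACTIVATIONS,
                 with_batchnorm: bool = False,
                 fusion_dropout: list[float] | None = None,
                 classifier_dropout: float = 0.0,
                 zero_features: dict[str, list[np.ndarray]] | None = None):
        ns = tuple(len(feature_dims[m]) for m in modalities)
        validate_config(config, ns, len(activations))
        self.modalities = modalities
        self.config = config
        self.n_classes = n_classes
        self.activation_names = activations
        self.zero_features = zero_features or {}
        widths = ([fusion_width] * len(config.layers)
                  if isinstance(fusion_width, int) else list(fusion_width))
        drops = fusion_dropout or [0.0] * len(config.layers)
        drop_rng = np.random.default_rng(rng.integers(2 ** 31))

        self._keys: list[tuple] = []
        self.fusion_layers = []
        prev_width = 0
        for l, spec in enumerate(config.layers):
            in_dim = sum(feature_dims[m][spec.modality_indices[i] - 1]
                         for i, m in enumerate(modalities)) + prev_width
            dense = nn.Dense(in_dim, widths[l], rng)
            key = shared_weight_key(l + 1, dense.W.value.shape,
                                    spec.activation_index)
            if store is not None and key in store:
                W, b = store.get(key)
                dense.W.value[...] = W
                dense.b.value[...] = b
            act = nn.ACTIVATIONS[activations[spec.activation_index - 1]]()
            bn = nn.BatchNorm(widths[l]) if with_batchnorm else None
            dropout = nn.Dropout(drops[l], drop_rng) if drops[l] > 0 else None
            self.fusion_layers.append((dense, act, bn, dropout))
            self._keys.append(key)
            prev_width = widths[l]

        self.clf_drop = (nn.Dropout(classifier_dropout, drop_rng)
                         if classifier_dropout > 0 else None)
        self.clf = nn.Dense(prev_width, n_classes, rng)
        self._clf_key = ("classifier", self.clf.W.value.shape, 0)
        if store is not None and self._clf_key in store:
            W, b = store.get(self._clf_key)
            self.clf.W.value[...] = W
            self.clf.b.value[...] = b
        self._store = store

    # -- forward / backward ---------------------------------------------------
    def _gather(self, feats: dict[str, list[np.ndarray]], spec: FusionLayerSpec,
                h_prev: np.ndarray | None) -> np.ndarray:
        parts = []
        for i, m in enumerate(self.modalities):
            f = feats[m][spec.modality_indices[i] - 1]
            if f.shape[1]:
                parts.append(f)
        if h_prev is not None:
            parts.append(h_prev)
        return np.concatenate(parts, axis=1) if parts else h_prev

    def forward(self, feats: dict[str, list[np.ndarray]],
                train: bool = False) -> np.ndarray:
        h = None
        self._split_dims = []
        for spec, (dense, act, bn, dropout) in zip(self.config.layers,
                                                   self.fusion_layers):
            z = self._gather(feats, spec, h)
            self._split_dims.append(z.shape[1] - (h.shape[1] if h is not None else 0))
            z = dense.forward(z, train)
            if bn is not None:
                z = bn.forward(z, train)
            z = act.forward(z)
            if dropout is not None:
                z = dropout.forward(z, train)
            h = z
        if self.clf_drop is not None:
            h = self.clf_drop.forward(h, train)
        self._logits = self.clf.forward(h, train)
        return nn.softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.clf.backward(dlogits)
        if self.clf_drop is not None:
            d = self.clf_drop.backward(d)
        for (dense, act, bn, dropout), feat_dim in zip(
                reversed(self.fusion_layers), reversed(self._split_dims)):
            if dropout is not None:
                d = dropout.backward(d)
            d = act.backward(d)
            if bn is not None:
                d = bn.backward(d)
            d = dense.backward(d)
            d = d[:, feat_dim:]  # gradient w.r.t. h_{l-1}; feature part is frozen

    def params(self) -> list[nn.Param]:
        ps = []
        for dense, act, bn, dropout in self.fusion_layers:
            ps.extend(dense.params())
            if bn is not None:
                ps.extend(bn.params())
        ps.extend(self.clf.params())
        return ps

    def get_weights(self) -> list[np.ndarray]:
        out = [p.value.copy() for p in self.params()]
        for dense, act, bn, dropout in self.fusion_layers:
            if bn is not None:
                out.extend([bn.run_mean.copy(), bn.run_var.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.params()
        for p, w in zip(ps, weights[:len(ps)]):
            p.value[...] = w
        rest = weights[len(ps):]
        i = 0
        for dense, act, bn, dropout in self.fusion_layers:
            if bn is not None:
                bn.run_mean[...] = rest[i]
                bn.run_var[...] = rest[i + 1]
                i += 2

    def write_back(self) -> None:
        """Publish current fusion/classifier weights to the shared store."""
        if self._store is None:
            return
        for key, (dense, *_rest) in zip(self._keys, self.fusion_layers):
            self._store.put(key, dense.W.value, dense.b.value)
        self._store.put(self._clf_key, self.clf.W.value, self.clf.b.value)


def backbone_feature_dims(backbones: dict) -> dict[str, list[int]]:
    return {m: [w for _, w in b.fusible_layers] for m, b in backbones.items()}


def build_fusion_network(backbones: dict, config: FusionConfig,
                         fusion_width: int | list[int], n_classes: int,
                         rng: np.random.Generator,
                         store: SharedWeightStore | None = None,
                         with_batchnorm: bool = False,
                         activations: tuple[str, ...] = DEFAULT_ACTIVATIONS,
                         zero_features: dict[str, list[np.ndarray]] | None = None,
                         **kwargs) -> FusionModel:
    """Build the trainable fusion head for a configuration.

    ``backbones`` maps modality -> a frozen backbone declaring
    ``fusible_layers``; only fusion and classifier weights are trainable.
    """
    modalities = list(backbones)
    return FusionModel(modalities, backbone_feature_dims(backbones), config,
                       fusion_width, n_classes, rng, store=store,
                       activations=activations, with_batchnorm=with_batchnorm,
                       zero_features=zero_features, **kwargs)


# ---------------------------------------------------------------------------
# feature caches
# ---------------------------------------------------------------------------

def extract_features(backbone, images: np.ndarray,
                     batch_size: int = 256) -> list[np.ndarray]:
    """Per-fusible-layer pooled features for a stack of images (frozen pass)."""
    parts = [backbone.fusible_features(images[s:s + batch_size])
             for s in range(0, len(images), batch_size)]
    return [np.concatenate([p[i] for p in parts], axis=0)
            for i in range(backbone.n_fusible)]


def zero_image_features(backbone, image_size: int) -> list[np.ndarray]:
    """Features the backbone emits for an all-zero (dropped/missing) input."""
    return [f[0] for f in backbone.fusible_features(
        np.zeros((1, image_size, image_size, 3)))]


def build_feature_cache(backbones: dict, records: list[dict], image_root: str,
                        image_size: int, loader=None) -> tuple[dict, np.ndarray, list[frozenset]]:
    """Cache per-record fusible features for every modality.

    ``records`` are multimodal index entries ({"label", "images": {organ:
    relative path}}).  Records missing a modality receive that backbone's
    zero-image features, making the missing-modality path identical to a
    multimodal-dropout zeroing.  Returns (feats, labels, modality_sets) where
    feats[m][layer] has shape (n_records, dim).
    """
    from .dataset import load_image
    loader = loader or load_image
    labels = np.array([r["label"] for r in records], dtype=int)
    modality_sets = [frozenset(r["images"]) for r in records]
    feats: dict[str, list[np.ndarray]] = {}
    for m, backbone in backbones.items():
        paths = sorted({r["images"][m] for r in records if m in r["images"]})
        path_idx = {p: i for i, p in enumerate(paths)}
        zf = zero_image_features(backbone, image_size)
        if paths:
            imgs = np.stack([loader(os.path.join(image_root, p), image_size)
                             for p in paths])
            per_image = extract_features(backbone, imgs)
        else:
            per_image = [np.zeros((0, len(z))) for z in zf]
        layers = []
        for li, z in enumerate(zf):
            arr = np.tile(z, (len(records), 1))
            for ri, r in enumerate(records):
                if m in r["images"]:
                    arr[ri] = per_image[li][path_idx[r["images"][m]]]
            layers.append(arr)
        feats[m] = layers
    return feats, labels, modality_sets


def subset_features(feats: dict[str, list[np.ndarray]], idx: np.ndarray,
                    subset: tuple[str, ...] | None = None,
                    zero_features: dict[str, list[np.ndarray]] | None = None) -> dict:
    """Restrict a cache to records ``idx``; modalities outside ``subset`` are
    replaced by zero-image features (the missing-modality input path)."""
    out = {}
    for m, layers in feats.items():
        if subset is None or m in subset:
            out[m] = [layer[idx] for layer in layers]
        else:
            zf = zero_features[m]
            out[m] = [np.tile(zf[li], (len(idx), 1)) for li in range(len(layers))]
    return out


# ---------------------------------------------------------------------------
# candidate scoring
# ---------------------------------------------------------------------------

def train_and_score_candidate(model: FusionModel, train_data, val_data,
                              epochs: int = 2, batch_size: int = 256,
                              lr: float = 1e-3, seed: int = 0,
                              buffer_size: int = 12) -> float:
    """Brief training of one candidate; returns validation macro F1.

    Trains only the fusion/classifier weights with the class-weighted loss on
    a fixed batch partition shuffled in buffers, then writes the trained
    weights back to the shared store.
    """
    train_feats, y_train = train_data
    val_feats, y_val = val_data
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("empty training or validation data")
    rng = np.random.default_rng(seed)
    cw = compute_class_weights(np.maximum(
        np.bincount(y_train, minlength=model.n_classes), 1))
    n = len(y_train)
    bounds = [(s, min(s + batch_size, n)) for s in range(0, n, batch_size)]
    opt = nn.Adam(model.params(), lr=lr)
    for _ in range(epochs):
        for b in _shuffle_in_buffers(len(bounds), buffer_size, rng):
            lo, hi = bounds[b]
            fb = {m: [layer[lo:hi] for layer in layers]
                  for m, layers in train_feats.items()}
            yb = y_train[lo:hi]
            probs = model.forward(fb, train=True)
            opt.zero_grad()
            model.backward(_ce_grad_logits(probs, yb, cw.per_sample(yb)))
            opt.step()
    model.write_back()
    val_probs = model.forward(val_feats, train=False)
    return f1_macro(np.argmax(val_probs, axis=1), y_val, model.n_classes)


# ---------------------------------------------------------------------------
# the search loop
# ---------------------------------------------------------------------------

def _extend_at_level(config: FusionConfig, spec: FusionLayerSpec,
                     level: int) -> FusionConfig:
    """Append ``spec`` if the config is shorter than ``level`` layers,
    otherwise replace its ``level``-th layer."""
    layers = config.layers
    if len(layers) < level:
        return FusionConfig(layers + (spec,))
    return FusionConfig(layers[:level - 1] + (spec,) + layers[level:])


def _config_to_json(config: FusionConfig) -> list[list[int]]:
    return [list(s.gamma) for s in config.layers]


def _config_from_json(data) -> FusionConfig:
    return FusionConfig(tuple(FusionLayerSpec(tuple(g)) for g in data))


def run_search(backbones: dict, train_data, val_data, *, iterations: int = 5,
               levels: int = 4, n_sampled: int = 50, seed: int = 0,
               fusion_width: int = 64, epochs_per_candidate: int = 2,
               batch_size: int = 256, n_classes: int | None = None,
               activations: tuple[str, ...] = DEFAULT_ACTIVATIONS,
               t_max: float = TEMPERATURE_DEFAULTS["t_max"],
               t_min: float = TEMPERATURE_DEFAULTS["t_min"],
               d: float = TEMPERATURE_DEFAULTS["d"],
               surrogate_epochs: int = 50,
               checkpoint_path: str | None = None,
               resume: bool = False) -> list[CandidateResult]:
    """Progressive surrogate-guided search; returns results sorted by score.

    The first (iteration, level) step enumerates every single-layer
    configuration exhaustively; each later step builds level-``l`` variants of
    the sampled set, scores them with the surrogate (known results override
    predictions), temperature-samples ``n_sampled`` of them, trains each for
    ``epochs_per_candidate`` epochs with shared weights, keeps the best score
    per configuration, and refits the surrogate on all results.  A checkpoint
    (JSON results + surrogate weights) is written after every level and can be
    resumed from.
    """
    train_feats, y_train = train_data
    modalities = list(backbones)
    ns = tuple(b.n_fusible for b in backbones.values())
    k = len(activations)
    if n_classes is None:
        n_classes = int(max(y_train)) + 1
    L = levels
    pool = enumerate_single_layer_configs(ns, k)

    ss = np.random.SeedSequence(seed)
    sample_rng, build_rng, score_seed_rng, surrogate_seed = ss.spawn(4)
    sample_rng = np.random.default_rng(sample_rng)
    build_rng = np.random.default_rng(build_rng)
    score_seed_rng = np.random.default_rng(score_seed_rng)
    surrogate_seed = int(np.random.default_rng(surrogate_seed).integers(2 ** 31))

    results: dict[FusionConfig, CandidateResult] = {}
    sampled_set: list[FusionConfig] = []
    surrogate: nn.LSTMRegressor | None = None
    store = SharedWeightStore()
    step = 0
    done_steps = 0

    if resume and checkpoint_path and os.path.exists(checkpoint_path):
        with open(checkpoint_path) as fh:
            ck = json.load(fh)
        for item in ck["results"]:
            cfg = _config_from_json(item["config"])
            results[cfg] = CandidateResult(cfg, item["score"], item["epochs"])
        sampled_set = [_config_from_json(c) for c in ck["sampled_set"]]
        step = ck["step"]
        done_steps = ck["done_steps"]
        wpath = checkpoint_path + ".surrogate.npz"
        if os.path.exists(wpath) and results:
            surrogate = nn.LSTMRegressor(vocab_size(ns, k), seed=surrogate_seed)
            with np.load(wpath) as data:
                surrogate.set_weights({n: data[n] for n in data.files})
        logger.info("resumed search at step %d with %d results", step, len(results))

    def checkpoint() -> None:
        if not checkpoint_path:
            return
        payload = {
            "results": [{"config": _config_to_json(c), "score": r.score,
                         "epochs": r.epochs_trained} for c, r in results.items()],
            "sampled_set": [_config_to_json(c) for c in sampled_set],
            "step": step,
            "done_steps": done_steps,
        }
        tmp = checkpoint_path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh)
        os.replace(tmp, checkpoint_path)
        if surrogate is not None:
            np.savez(checkpoint_path + ".surrogate.npz", **surrogate.get_weights())

    def score_candidates(candidates: list[FusionConfig]) -> None:
        nonlocal sampled_set
        for cfg in candidates:
            model = build_fusion_network(
                backbones, cfg, fusion_width, n_classes, build_rng, store=store,
                activations=activations)
            score = train_and_score_candidate(
                model, (train_feats, y_train), val_data,
                epochs=epochs_per_candidate, batch_size=batch_size,
                seed=int(score_seed_rng.integers(2 ** 31)))
            prev = results.get(cfg)
            if prev is None or score > prev.score:
                results[cfg] = CandidateResult(cfg, score, epochs_per_candidate)
        sampled_set = list(candidates)

    step_index = 0
    for _iteration in range(iterations):
        for level in range(1, levels + 1):
            if step_index < done_steps:
                step_index += 1
                continue
            if step_index == 0:
                # exhaustive first level
                singles = [FusionConfig((s,)) for s in pool]
                score_candidates(singles)
                # the progression continues from a temperature-sampled subset
                scores = np.array([results[c].score for c in singles])
                t = temperature_at_step(step, t_max, t_min, d)
                step += 1
                take = min(n_sampled, len(singles))
                idx = sample_with_temperature(scores, t, take, sample_rng)
                sampled_set = [singles[i] for i in idx]
            else:
                candidates: list[FusionConfig] = []
                seen = set()
                for cfg in sampled_set:
                    for spec in pool:
                        new = _extend_at_level(cfg, spec, level)
                        if new not in seen:
                            seen.add(new)
                            candidates.append(new)
                preds = surrogate_score(surrogate, candidates, ns, k, L)
                preds = np.clip(preds, 0.0, 1.0)
                for i, cfg in enumerate(candidates):
                    if cfg in results:  # known scores override predictions
                        preds[i] = results[cfg].score
                t = temperature_at_step(step, t_max, t_min, d)
                step += 1
                take = min(n_sampled, len(candidates))
                idx = sample_with_temperature(preds, t, take, sample_rng)
                score_candidates([candidates[i] for i in idx])
            surrogate = surrogate_fit(
                {c: r.score for c, r in results.items()}, ns, k, L,
                surrogate_seed, surrogate=surrogate, epochs=surrogate_epochs)
            step_index += 1
            done_steps = step_index
            checkpoint()

    ranked = sorted(results.values(),
                    key=lambda r: (-r.score, _config_to_json(r.config)))
    return ranked
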