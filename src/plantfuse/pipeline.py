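"""End-to-end study: data -> backbones -> search -> final models -> evaluation.

Runs the whole method on a synthetic observation-grouped organ-image dataset:

1. generate the dataset and preprocess it into unimodal + multimodal splits;
2. train one tiny CNN backbone per organ with the class-weighted loss;
3. cache frozen backbone features and run the fusion architecture search;
4. train the best configuration to convergence twice — with and without
   multimodal dropout;
5. evaluate both variants against the late-fusion baseline, overall and on
   every modality subset.

Problem sizes default to desk scale (10 classes, 32x32 images, a few hundred
observations, a 2x2 search schedule sampling 12 architectures per step) so a
full study completes in minutes on one CPU core.
"""

from __future__ import annotations

import itertools
import json
import logging
import os

import numpy as np

from .dataset import build_dataset, load_image, load_index
from .evaluation import (compute_metrics, evaluate_modality_subsets, f1_macro,
                         late_fusion_probs, mcnemar_test)
from .search import (build_feature_cache, build_fusion_network, run_search,
                     subset_features, zero_image_features)
from .synthetic import ORGANS, SyntheticSpec, generate_dataset
from .training import (DEFAULT_AUGMENTATIONS, MultimodalDropoutSpec,
                       TinyCNNBackbone, TrainSpec, train_multimodal,
                       train_unimodal)

logger = logging.getLogger(__name__)


def _load_split(data_dir: str, organ: str, split: str, image_size: int):
    entries = load_index(os.path.join(data_dir, "unimodal", organ,
                                      f"{split}.jsonl"))
    if not entries:
        return np.zeros((0, image_size, image_size, 3)), np.zeros(0, dtype=int)
    x = np.stack([load_image(os.path.join(data_dir, e["path"]), image_size)
                  for e in entries])
    y = np.array([e["label"] for e in entries], dtype=int)
    return x, y


def train_backbones(data_dir: str, n_classes: int, image_size: int, seed: int,
                    spec: TrainSpec | None = None) -> tuple[dict, dict]:
    """Train one backbone per organ; returns (backbones, unimodal test metrics)."""
    spec = spec or TrainSpec(initial_lr=1e-3, epochs=30, es_patience=8,
                             batch_size=32)
    ss = np.random.SeedSequence(seed)
    seeds = [int(np.random.default_rng(s).integers(2 ** 31)) for s in ss.spawn(len(ORGANS))]
    backbones, metrics = {}, {}
    for organ, organ_seed in zip(ORGANS, seeds):
        x_train, y_train = _load_split(data_dir, organ, "train", image_size)
        x_val, y_val = _load_split(data_dir, organ, "val", image_size)
        x_test, y_test = _load_split(data_dir, organ, "test", image_size)
        model = TinyCNNBackbone(organ, n_classes, seed=organ_seed)
        train_unimodal(model, x_train, y_train, x_val, y_val, spec,
                       seed=organ_seed, augment=DEFAULT_AUGMENTATIONS[organ])
        backbones[organ] = model
        if len(y_test):
            metrics[organ] = compute_metrics(model.forward(x_test), y_test,
                                             top_ns=(1, 5))
        logger.info("backbone %s: test %s", organ, metrics.get(organ))
    return backbones, metrics


def _unimodal_probs_on_records(backbones: dict, records: list[dict],
                               data_dir: str, image_size: int) -> dict[str, np.ndarray]:
    """Per-organ unimodal probabilities for each multimodal record's image.

    Records lacking an organ get uniform rows; the baseline never consults
    them because the organ's model is excluded from the late-fusion average.
    """
    n_classes = next(iter(backbones.values())).n_classes
    out = {}
    for organ, model in backbones.items():
        probs = np.full((len(records), n_classes), 1.0 / n_classes)
        paths = sorted({r["images"][organ] for r in records
                        if organ in r["images"]})
        if paths:
            imgs = np.stack([load_image(os.path.join(data_dir, p), image_size)
                             for p in paths])
            path_probs = {}
            for s in range(0, len(imgs), 256):
                block = model.forward(imgs[s:s + 256])
                for j, p in enumerate(paths[s:s + 256]):
                    path_probs[p] = block[j]
            for i, r in enumerate(records):
                if organ in r["images"]:
                    probs[i] = path_probs[r["images"][organ]]
        out[organ] = probs
    return out


def all_modality_subsets(organs: tuple[str, ...] = ORGANS) -> list[tuple[str, ...]]:
    subsets = []
    for r in range(1, len(organs) + 1):
        subsets.extend(itertools.combinations(organs, r))
    return subsets


def run_study(seed: int, workdir: str, *, n_classes: int = 10,
              image_size: int = 32, max_observations: int = 30,
              iterations: int = 2, levels: int = 2, n_sampled: int = 12,
              fusion_width: int = 64, final_epochs: int = 60,
              md_rate: float = 0.125, backbone_epochs: int = 30) -> dict:
    """Run the complete scaled-down study; returns a results dictionary."""
    os.makedirs(workdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    (data_seed, split_seed, backbone_seed, search_seed,
     final_seed) = (int(np.random.default_rng(s).integers(2 ** 31))
                    for s in ss.spawn(5))

    # 1. data
    raw_dir = os.path.join(workdir, "raw")
    spec = SyntheticSpec(n_classes=n_classes, image_size=image_size,
                         max_observations=max_observations, seed=data_seed)
    generate_dataset(spec, raw_dir)
    data_dir = os.path.join(workdir, "data")
    manifest = build_dataset(os.path.join(raw_dir, "metadata.csv"), data_dir,
                             seed=split_seed, image_size=image_size)
    n_out_classes = manifest["n_classes"]

    # 2. backbones
    backbone_spec = TrainSpec(initial_lr=1e-3, epochs=backbone_epochs,
                              es_patience=8, batch_size=32)
    backbones, unimodal_metrics = train_backbones(
        data_dir, n_out_classes, image_size, backbone_seed, backbone_spec)

    # 3. feature caches
    splits = {}
    for split in ("train", "val", "test"):
        records = load_index(os.path.join(data_dir, "multimodal",
                                          f"{split}.jsonl"))
        feats, labels, modality_sets = build_feature_cache(
            backbones, records, data_dir, image_size)
        splits[split] = {"records": records, "feats": feats, "labels": labels,
                         "modality_sets": modality_sets}
    zero_feats = {m: zero_image_features(b, image_size)
                  for m, b in backbones.items()}

    # 4. search
    ranked = run_search(
        backbones,
        (splits["train"]["feats"], splits["train"]["labels"]),
        (splits["val"]["feats"], splits["val"]["labels"]),
        iterations=iterations, levels=levels, n_sampled=n_sampled,
        seed=search_seed, fusion_width=fusion_width, batch_size=64,
        n_classes=n_out_classes,
        checkpoint_path=os.path.join(workdir, "search.json"))
    best = ranked[0]
    logger.info("search best config %s score %.4f", best.config, best.score)

    # 5. final training, with and without multimodal dropout
    final_spec = TrainSpec(initial_lr=5e-4, decay_rate=0.9, decay_steps=200,
                           batch_size=64, epochs=final_epochs, es_patience=10)
    variants = {}
    for name, rate in (("no_md", 0.0), ("md", md_rate)):
        rng = np.random.default_rng(final_seed)
        model = build_fusion_network(
            backbones, best.config, fusion_width, n_out_classes, rng,
            with_batchnorm=True, zero_features=zero_feats)
        train_multimodal(
            model, splits["train"]["feats"], splits["train"]["labels"],
            splits["val"]["feats"], splits["val"]["labels"], final_spec,
            md_spec=MultimodalDropoutSpec(rate) if rate > 0 else None,
            seed=final_seed)
        variants[name] = model

    # 6. evaluation on the multimodal test split
    test = splits["test"]
    test_probs = {name: model.forward(test["feats"], train=False)
                  for name, model in variants.items()}
    unimodal_probs = _unimodal_probs_on_records(backbones, test["records"],
                                                data_dir, image_size)
    base_probs_rows = np.stack([
        late_fusion_probs([unimodal_probs[o][i] for o in test["modality_sets"][i]])
        for i in range(len(test["labels"]))])

    overall = {name: compute_metrics(p, test["labels"], top_ns=(1, 5))
               for name, p in test_probs.items()}
    overall["baseline"] = compute_metrics(base_probs_rows, test["labels"],
                                          top_ns=(1, 5))
    y = test["labels"]
    mcnemar = {
        name: vars(mcnemar_test(np.argmax(p, 1) == y,
                                np.argmax(base_probs_rows, 1) == y))
        for name, p in test_probs.items()
    }

    # 7. modality-subset evaluation for both variants
    subsets = all_modality_subsets()
    subset_rows = {}
    for name, model in variants.items():
        def proposed(idx, subset, _model=model):
            feats = subset_features(test["feats"], idx, subset, zero_feats)
            return _model.forward(feats, train=False)
        subset_rows[name] = evaluate_modality_subsets(
            y, test["modality_sets"], proposed, unimodal_probs, subsets,
            n_out_classes)

    results = {
        "seed": seed,
        "manifest": manifest,
        "unimodal_test_metrics": unimodal_metrics,
        "search_best_score": best.score,
        "search_best_config": [list(s.gamma) for s in best.config.layers],
        "n_configs_evaluated": len(ranked),
        "test_metrics": overall,
        "mcnemar_vs_baseline": mcnemar,
        "subset_f1": subset_rows,
    }
    with open(os.path.join(workdir, "study.json"), "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    return results


def summarize_pattern(results: dict) -> dict:
    """Reduce a study to the qualitative comparisons of interest."""
    uni_f1 = {o: m["f1_macro"]
              for o, m in results["unimodal_test_metrics"].items()}
    t = results["test_metrics"]
    singles_md, singles_nomd = [], []
    all_md = all_nomd = None
    for row_md, row_nomd in zip(results["subset_f1"]["md"],
                                results["subset_f1"]["no_md"]):
        subset = tuple(row_md["subset"])
        if row_md.get("f1_macro_proposed") is None or row_md["n_predictions"] == 0:
            continue
        if len(subset) == 1:
            singles_md.append(row_md["f1_macro_proposed"])
            singles_nomd.append(row_nomd["f1_macro_proposed"])
        elif len(subset) == len(ORGANS):
            all_md = row_md["f1_macro_proposed"]
            all_nomd = row_nomd["f1_macro_proposed"]
    return {
        "multimodal_f1": t["no_md"]["f1_macro"],
        "multimodal_md_f1": t["md"]["f1_macro"],
        "baseline_f1": t["baseline"]["f1_macro"],
        "best_unimodal_f1": max(uni_f1.values()) if uni_f1 else np.nan,
        "unimodal_f1": uni_f1,
        "beats_all_unimodal": t["no_md"]["f1_macro"] > max(uni_f1.values()),
        "beats_baseline": t["no_md"]["f1_macro"] > t["baseline"]["f1_macro"],
        "single_subset_mean_md": float(np.mean(singles_md)),
        "single_subset_mean_no_md": float(np.mean(singles_nomd)),
        "md_wins_single_subsets": float(np.mean(singles_md)) > float(np.mean(singles_nomd)),
        "no_md_wins_full_subset": (all_nomd is not None and all_md is not None
                                   and all_nomd > all_md),
        "full_subset_md": all_md,
        "full_subset_no_md": all_nomd,
    }
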