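"""Observation-grouped dataset preprocessing.

Converts a metadata table of plant-organ images grouped by observation
(one physical specimen, arbitrarily many photos of its flower / leaf / fruit /
stem) into:

* per-organ unimodal train/val/test datasets for backbone pre-training, and
* a fixed-input multimodal dataset whose records map each organ present in a
  class to one image.

Splitting happens *by observation* (never by image, to avoid leakage) and is
framed per class as a constrained binary optimisation: choose one split per
observation so that both observation counts and per-organ image counts match
the target fractions as closely as possible, i.e. minimise

    sum_s (|x_s| - lambda_s N)^2  +  sum_o sum_s (c_o . x_s - lambda_s |c_o|)^2

subject to each observation landing in exactly one split.  Solved exactly by
enumeration for small classes and by a deterministic greedy + relocation local
search for large ones.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import ORGANS

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")
DEFAULT_LAMBDAS = (0.6, 0.2, 0.2)

#: classes are enumerable exactly up to this many observations (|S|^N states)
EXHAUSTIVE_LIMIT = 12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ObservationRecord:
    """One specimen: its class label and per-organ image references."""

    observation_id: str
    class_id: int
    organ_images: dict[str, list[str]] = field(default_factory=dict)

    def total_images(self) -> int:
        return sum(len(v) for v in self.organ_images.values())


@dataclass
class SplitProblem:
    """One class's split-assignment instance."""

    n_observations: int
    lambdas: tuple[float, ...] = DEFAULT_LAMBDAS
    splits: tuple[str, ...] = SPLITS
    organ_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_observations < 1:
            raise ValueError("split problem needs at least one observation")
        lam = np.asarray(self.lambdas, dtype=float)
        if len(self.lambdas) != len(self.splits) or np.any(lam < 0) \
                or abs(lam.sum() - 1.0) > 1e-9:
            raise ValueError("lambdas must be nonnegative and sum to 1")
        for o, c in self.organ_counts.items():
            c = np.asarray(c)
            if len(c) != self.n_observations or np.any(c < 0):
                raise ValueError(f"organ count vector for {o!r} is malformed")


@dataclass
class SplitAssignment:
    """Split index per observation plus the achieved objective value."""

    assignment: np.ndarray  # int vector, values index into problem.splits
    objective_value: float

    def decision_vectors(self, n_splits: int) -> np.ndarray:
        """Binary matrix x with x[s, i] = 1 iff observation i is in split s."""
        x = np.zeros((n_splits, len(self.assignment)), dtype=int)
        x[self.assignment, np.arange(len(self.assignment))] = 1
        return x


@dataclass
class MultimodalRecord:
    """A fixed-input training instance: one image per present modality."""

    modality_images: dict[str, str]
    class_id: int


# ---------------------------------------------------------------------------
# loading and filtering
# ---------------------------------------------------------------------------

def load_metadata(metadata_csv: str, root: str | None = None) -> list[ObservationRecord]:
    """Read a metadata CSV into observation records grouped by specimen."""
    meta = pd.read_csv(metadata_csv)
    required = {"observation_id", "class_id", "organ", "image_path"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    if root is None:
        root = os.path.dirname(os.path.abspath(metadata_csv))
    records: dict[tuple[int, str], ObservationRecord] = {}
    for row in meta.itertuples(index=False):
        key = (int(row.class_id), str(row.observation_id))
        rec = records.get(key)
        if rec is None:
            rec = records[key] = ObservationRecord(str(row.observation_id),
                                                   int(row.class_id))
        rec.organ_images.setdefault(str(row.organ), []).append(
            os.path.join(root, str(row.image_path)))
    return [records[k] for k in sorted(records)]


def filter_dataset(records: list[ObservationRecord], min_organ_images: int = 3,
                   min_observations: int = 3) -> list[ObservationRecord]:
    """Drop under-represented organs and classes.

    Within each class, an organ whose total image count is below
    ``min_organ_images`` cannot be split across train/val/test, so all its
    images are removed; observations left empty are removed; classes with
    fewer than ``min_observations`` observations are removed.
    """
    by_class: dict[int, list[ObservationRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.class_id, []).append(rec)

    out: list[ObservationRecord] = []
    for class_id in sorted(by_class):
        recs = sorted(by_class[class_id], key=lambda r: r.observation_id)
        totals: dict[str, int] = {}
        for rec in recs:
            for organ, imgs in rec.organ_images.items():
                totals[organ] = totals.get(organ, 0) + len(imgs)
        keep_organs = {o for o, n in totals.items() if n >= min_organ_images}
        kept = []
        for rec in recs:
            organ_images = {o: list(v) for o, v in rec.organ_images.items()
                            if o in keep_organs and v}
            if organ_images:
                kept.append(ObservationRecord(rec.observation_id, class_id,
                                              organ_images))
        if len(kept) >= min_observations:
            out.extend(kept)
    return out


# ---------------------------------------------------------------------------
# split optimisation
# ---------------------------------------------------------------------------

def split_objective(problem: SplitProblem, assignment: np.ndarray) -> float:
    """Evaluate the split objective at a given assignment vector."""
    assignment = np.asarray(assignment)
    n = problem.n_observations
    obj = 0.0
    for s, lam in enumerate(problem.lambdas):
        in_s = assignment == s
        obj += (in_s.sum() - lam * n) ** 2
        for c in problem.organ_counts.values():
            obj += (float(np.asarray(c)[in_s].sum()) - lam * float(np.sum(c))) ** 2
    return float(obj)


def _objective_components(problem: SplitProblem):
    n = problem.n_observations
    lam = np.asarray(problem.lambdas)
    vecs = [np.ones(n, dtype=float)]
    targets = [lam * n]
    for c in problem.organ_counts.values():
        c = np.asarray(c, dtype=float)
        vecs.append(c)
        targets.append(lam * c.sum())
    return np.stack(vecs), np.stack(targets)  # (K, N), (K, S)


def _exhaustive_split(problem: SplitProblem) -> SplitAssignment:
    n, n_splits = problem.n_observations, len(problem.splits)
    vecs, targets = _objective_components(problem)
    total = n_splits ** n
    best_obj = np.inf
    best: np.ndarray | None = None
    chunk = 1 << 16
    # assignments enumerated in lexicographic order (obs 0 most significant)
    # so argmin keeps the lexicographically smallest optimum
    powers = n_splits ** np.arange(n - 1, -1, -1, dtype=np.int64)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        assign = (idx[:, None] // powers[None, :]) % n_splits  # (B, N)
        obj = np.zeros(len(idx))
        for s in range(n_splits):
            mask = (assign == s).astype(float)  # (B, N)
            sums = mask @ vecs.T  # (B, K)
            obj += ((sums - targets[:, s]) ** 2).sum(axis=1)
        j = int(np.argmin(obj))
        if obj[j] < best_obj - 1e-12:
            best_obj = float(obj[j])
            best = assign[j].copy()
    assert best is not None
    return SplitAssignment(best.astype(int), best_obj)


def _local_search_split(problem: SplitProblem) -> SplitAssignment:
    n, n_splits = problem.n_observations, len(problem.splits)
    vecs, targets = _objective_components(problem)  # (K, N), (K, S)
    sums = np.zeros_like(targets)  # (K, S) current component sums per split

    # deterministic greedy: heaviest observations first
    weights = vecs[1:].sum(axis=0) if len(vecs) > 1 else vecs[0]
    order = sorted(range(n), key=lambda i: (-weights[i], i))
    assignment = np.zeros(n, dtype=int)
    for i in order:
        best_s, best_delta = 0, np.inf
        for s in range(n_splits):
            delta = float(((sums[:, s] + vecs[:, i] - targets[:, s]) ** 2
                           - (sums[:, s] - targets[:, s]) ** 2).sum())
            if delta < best_delta - 1e-12:
                best_s, best_delta = s, delta
        assignment[i] = best_s
        sums[:, best_s] += vecs[:, i]

    # relocation passes: move one observation at a time while it helps
    for _ in range(200):
        improved = False
        for i in range(n):
            cur = assignment[i]
            for s in range(n_splits):
                if s == cur:
                    continue
                old = (((sums[:, cur] - targets[:, cur]) ** 2).sum()
                       + ((sums[:, s] - targets[:, s]) ** 2).sum())
                new = (((sums[:, cur] - vecs[:, i] - targets[:, cur]) ** 2).sum()
                       + ((sums[:, s] + vecs[:, i] - targets[:, s]) ** 2).sum())
                if new < old - 1e-9:
                    sums[:, cur] -= vecs[:, i]
                    sums[:, s] += vecs[:, i]
                    assignment[i] = s
                    cur = s
                    improved = True
        if not improved:
            break
    return SplitAssignment(assignment, split_objective(problem, assignment))


def optimize_split(problem: SplitProblem,
                   exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> SplitAssignment:
    """Solve the per-class split assignment.

    Exact (global minimum, lexicographically smallest optimum) for classes
    with at most ``exhaustive_limit`` observations; otherwise a deterministic
    greedy construction refined by single-observation relocations.
    """
    problem.validate()
    if problem.n_observations <= exhaustive_limit:
        return _exhaustive_split(problem)
    return _local_search_split(problem)


def repair_empty_splits(split_images: dict[str, dict[str, list[str]]],
                        splits: tuple[str, ...] = SPLITS) -> dict[str, dict[str, list[str]]]:
    """Ensure every split holds at least one image of every organ the class has.

    Mutates a copy: whenever a split holds zero images of an organ, one image
    is transferred from the split currently holding the most images of that
    organ (ties resolved in split order, train first).  If the class has fewer
    images of the organ than there are splits the repair is impossible; a
    warning is logged and the remaining splits stay empty.
    """
    out = {s: {o: list(v) for o, v in split_images.get(s, {}).items() if v}
           for s in splits}
    organs = sorted({o for s in splits for o in out[s]})
    for organ in organs:
        total = sum(len(out[s].get(organ, [])) for s in splits)
        if total and total < len(splits):
            logger.warning(
                "cannot fully repair organ %r: only %d image(s) for %d splits",
                organ, total, len(splits))
        while True:
            c = {s: len(out[s].get(organ, [])) for s in splits}
            empty = [s for s in splits if c[s] == 0]
            if not empty:
                break
            donor = max(splits, key=lambda s: (c[s], -splits.index(s)))
            if c[donor] < 2:  # best effort exhausted (pigeonhole)
                break
            img = out[donor][organ].pop()
            out[empty[0]].setdefault(organ, []).append(img)
    return out


# ---------------------------------------------------------------------------
# multimodal record generation
# ---------------------------------------------------------------------------

def generate_multimodal_records(organ_images: dict[str, list[str]], class_id: int,
                                rng: np.random.Generator) -> list[MultimodalRecord]:
    """Pair organ images into N = max(n_flower, n_leaf, n_fruit, n_stem) records.

    Each present organ's image list is permuted and tiled cyclically to length
    N, so every image appears floor(N/n) or ceil(N/n) times; organs absent
    from the class contribute no key.  The resulting records are shuffled.
    """
    present = {o: v for o, v in organ_images.items() if v}
    if not present:
        raise ValueError("cannot generate multimodal records: no images at all")
    n_max = max(len(v) for v in present.values())
    columns = {}
    for organ in ORGANS:
        if organ in present:
            perm = [present[organ][j] for j in rng.permutation(len(present[organ]))]
            columns[organ] = [perm[i % len(perm)] for i in range(n_max)]
    records = [MultimodalRecord({o: columns[o][i] for o in columns}, class_id)
               for i in range(n_max)]
    return [records[j] for j in rng.permutation(n_max)]


# ---------------------------------------------------------------------------
# image export and loading
# ---------------------------------------------------------------------------

def export_image(src: str, dst: str, size: int) -> bool:
    """Re-encode one image: RGB, bilinear resize to size x size, JPEG q95."""
    try:
        img = Image.open(src).convert("RGB")
    except (OSError, ValueError):
        logger.warning("skipping unreadable image %s", src)
        return False
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    img.save(dst, format="JPEG", quality=95)
    return True


def load_image(path: str, size: int | None = None) -> np.ndarray:
    """Load an exported image as float NHWC-compatible array in [-1, 1]."""
    img = Image.open(path).convert("RGB")
    if size is not None and img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def load_index(path: str) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_dataset(metadata_csv: str, out_dir: str, seed: int = 42,
                  image_size: int = 32,
                  lambdas: tuple[float, ...] = DEFAULT_LAMBDAS,
                  min_organ_images: int = 3, min_observations: int = 3) -> dict:
    """Run the preprocessing pipeline end to end; returns the manifest dict.

    Steps: group by observation, filter organs/classes, per-class split
    optimisation, empty-split repair, unimodal export per organ, multimodal
    record generation and export.  Output layout::

        out_dir/images/*.jpg                 re-encoded images
        out_dir/unimodal/<organ>/<split>.jsonl
        out_dir/multimodal/<split>.jsonl
        out_dir/manifest.json
    """
    records = filter_dataset(load_metadata(metadata_csv),
                             min_organ_images, min_observations)
    if not records:
        raise ValueError("no classes survive filtering")

    class_ids = sorted({r.class_id for r in records})
    label_map = {c: i for i, c in enumerate(class_ids)}

    ss = np.random.SeedSequence(seed)
    pair_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    # --- per-class split optimisation + repair -----------------------------
    by_class: dict[int, list[ObservationRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.class_id, []).append(rec)

    # class -> split -> organ -> [image paths]
    class_split_images: dict[int, dict[str, dict[str, list[str]]]] = {}
    split_obs_counts = {s: 0 for s in SPLITS}
    for class_id in class_ids:
        recs = sorted(by_class[class_id], key=lambda r: r.observation_id)
        organs = sorted({o for r in recs for o in r.organ_images})
        problem = SplitProblem(
            n_observations=len(recs), lambdas=lambdas, splits=SPLITS,
            organ_counts={o: np.array([len(r.organ_images.get(o, []))
                                       for r in recs]) for o in organs})
        solution = optimize_split(problem)
        split_images: dict[str, dict[str, list[str]]] = {s: {} for s in SPLITS}
        for rec, s_idx in zip(recs, solution.assignment):
            split = SPLITS[s_idx]
            split_obs_counts[split] += 1
            for organ, imgs in rec.organ_images.items():
                split_images[split].setdefault(organ, []).extend(imgs)
        class_split_images[class_id] = repair_empty_splits(split_images)

    # --- image export (one re-encoded copy per referenced source image) ----
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    all_sources = sorted({p for cs in class_split_images.values()
                          for so in cs.values() for v in so.values() for p in v})
    exported: dict[str, str] = {}
    n_skipped = 0
    for i, src in enumerate(all_sources):
        dst = os.path.join(img_dir, f"img{i:06d}.jpg")
        if export_image(src, dst, image_size):
            exported[src] = os.path.join("images", f"img{i:06d}.jpg")
        else:
            n_skipped += 1

    def usable(paths: list[str]) -> list[str]:
        return [exported[p] for p in paths if p in exported]

    # --- unimodal datasets --------------------------------------------------
    unimodal_counts: dict[str, dict[str, int]] = {}
    for organ in ORGANS:
        organ_dir = os.path.join(out_dir, "unimodal", organ)
        os.makedirs(organ_dir, exist_ok=True)
        unimodal_counts[organ] = {}
        for split in SPLITS:
            entries = []
            for class_id in class_ids:
                for path in usable(class_split_images[class_id][split].get(organ, [])):
                    entries.append({"label": label_map[class_id], "path": path})
            order = shuffle_rng.permutation(len(entries))
            entries = [entries[j] for j in order]
            unimodal_counts[organ][split] = len(entries)
            with open(os.path.join(organ_dir, f"{split}.jsonl"), "w") as fh:
                for e in entries:
                    fh.write(json.dumps(e) + "\n")

    # --- multimodal datasets -------------------------------------------------
    mm_dir = os.path.join(out_dir, "multimodal")
    os.makedirs(mm_dir, exist_ok=True)
    multimodal_counts = {}
    for split in SPLITS:
        entries = []
        for class_id in class_ids:
            organ_images = {o: usable(v)
                            for o, v in class_split_images[class_id][split].items()}
            organ_images = {o: v for o, v in organ_images.items() if v}
            if not organ_images:
                continue
            for rec in generate_multimodal_records(organ_images, class_id, pair_rng):
                entries.append({"label": label_map[class_id],
                                "images": rec.modality_images})
        order = shuffle_rng.permutation(len(entries))
        entries = [entries[j] for j in order]
        multimodal_counts[split] = len(entries)
        with open(os.path.join(mm_dir, f"{split}.jsonl"), "w") as fh:
            for e in entries:
                fh.write(json.dumps(e) + "\n")

    manifest = {
        "seed": seed,
        "image_size": image_size,
        "n_classes": len(class_ids),
        "label_map": {str(c): i for c, i in label_map.items()},
        "split_observation_counts": split_obs_counts,
        "unimodal_counts": unimodal_counts,
        "multimodal_counts": multimodal_counts,
        "skipped_images": n_skipped,
        "lambdas": list(lambdas),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
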