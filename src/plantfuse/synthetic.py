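"""Seeded synthetic multi-organ plant image datasets.

Real multi-organ collections are observation-grouped (one specimen, many
photos), long-tailed in class size, and skewed in organ availability: flowers
are photographed for most species, stems for few, and some species lack whole
organs in the data.  This module emulates exactly that statistical shape with
cheap parametric renderings, so the full preprocessing / search / training /
evaluation pipeline can run and be tested end-to-end without any download.

The class signal is carried by a per-class hue (plus a stripe texture), the
organ determines a shape template, and each organ adds its own level of hue
jitter and pixel noise — flowers are the most reliable cue and stems the
least, mirroring how discriminative the organs are in real photographs.
"""

from __future__ import annotations

import colorsys
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

ORGANS = ("flower", "leaf", "fruit", "stem")

#: per-organ hue jitter (radians) — how unreliable the colour cue is per organ
DEFAULT_HUE_JITTER = {"flower": 0.22, "leaf": 0.35, "fruit": 0.55, "stem": 0.85}
DEFAULT_PIXEL_NOISE = 0.06


def _default_avail() -> dict[str, float]:
    return {"flower": 0.90, "leaf": 0.75, "fruit": 0.55, "stem": 0.40}


def _default_gate() -> dict[str, float]:
    return {"flower": 1.0, "leaf": 0.95, "fruit": 0.85, "stem": 0.75}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic observation-grouped organ-image dataset.

    ``organ_avail`` is the per-observation probability that a specimen carries
    at least one image of an organ; ``organ_class_gate`` additionally lets a
    class lack an organ entirely (gates < 1 reproduce the situation where many
    species have no stem or fruit photographs at all).
    """

    n_classes: int = 10
    class_size_tail: float = 0.7
    organ_avail: dict[str, float] = field(default_factory=_default_avail)
    organ_class_gate: dict[str, float] = field(default_factory=_default_gate)
    images_per_organ_lambda: float = 0.6
    max_observations: int = 30
    min_observations: int = 4
    image_size: int = 32
    hue_jitter: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HUE_JITTER))
    pixel_noise: float = DEFAULT_PIXEL_NOISE
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be a positive count")
        if self.class_size_tail < 0:
            raise ValueError("class_size_tail must be >= 0")
        for name, mapping in (("organ_avail", self.organ_avail),
                              ("organ_class_gate", self.organ_class_gate)):
            if set(mapping) != set(ORGANS):
                raise ValueError(f"{name} keys must be exactly {set(ORGANS)}")
            for o, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{o}] must be in [0, 1]")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.images_per_organ_lambda < 0:
            raise ValueError("images_per_organ_lambda must be >= 0")
        if self.min_observations < 1 or self.max_observations < self.min_observations:
            raise ValueError("max_observations must be >= min_observations >= 1")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _organ_mask(organ: str, size: int) -> np.ndarray:
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    if organ == "flower":
        mask = xx ** 2 + yy ** 2 <= 0.30 ** 2
        for ang in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            cx, cy = 0.45 * np.cos(ang), 0.45 * np.sin(ang)
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= 0.22 ** 2
    elif organ == "leaf":
        c, s = np.cos(0.5), np.sin(0.5)
        u, v = c * xx + s * yy, -s * xx + c * yy
        mask = (u / 0.75) ** 2 + (v / 0.35) ** 2 <= 1.0
    elif organ == "fruit":
        mask = (xx - 0.15) ** 2 + (yy + 0.1) ** 2 <= 0.33 ** 2
        mask |= (xx + 0.25) ** 2 + (yy - 0.25) ** 2 <= 0.18 ** 2
    elif organ == "stem":
        mask = np.abs(xx + 0.15 * np.sin(3.0 * yy)) <= 0.16
    else:
        raise ValueError(f"unknown organ tag: {organ!r}")
    return mask.astype(np.float64)


def render_organ_image(class_id: int, organ: str, rng: np.random.Generator,
                       n_classes: int, size: int = 32,
                       hue_jitter: float | None = None,
                       pixel_noise: float = DEFAULT_PIXEL_NOISE) -> np.ndarray:
    """Render one organ image as a float RGB array in [0, 1].

    The class fixes a hue on the colour circle and a stripe frequency; the
    organ fixes the shape template and (by default) the hue jitter level.
    Identical arguments and generator state yield identical images.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ tag: {organ!r}")
    if hue_jitter is None:
        hue_jitter = DEFAULT_HUE_JITTER[organ]
    theta = 2.0 * np.pi * class_id / max(n_classes, 1)
    theta = theta + rng.normal(0.0, hue_jitter)
    hue = (theta / (2.0 * np.pi)) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.85, 0.9)

    mask = _organ_mask(organ, size)
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    freq = 3.0 + (class_id % 4)
    stripes = 0.85 + 0.15 * np.sin(freq * np.pi * (xx + yy))

    img = np.empty((size, size, 3))
    background = 0.15 + 0.05 * yy
    for ch, col in enumerate((r, g, b)):
        img[:, :, ch] = background * (1.0 - mask) + col * stripes * mask
    if pixel_noise > 0:
        img = img + rng.normal(0.0, pixel_noise, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# observation structure
# ---------------------------------------------------------------------------

def class_sizes(spec: SyntheticSpec) -> np.ndarray:
    """Observations per class: truncated Zipf profile, non-increasing."""
    ranks = np.arange(1, spec.n_classes + 1, dtype=np.float64)
    sizes = spec.max_observations * ranks ** (-spec.class_size_tail)
    return np.maximum(np.round(sizes).astype(int), spec.min_observations)


def sample_structure(spec: SyntheticSpec, rng: np.random.Generator) -> list[dict]:
    """Sample the observation/organ/image-count structure without rendering.

    Returns one dict per observation: ``{"observation_id", "class_id",
    "organ_counts": {organ: n_images}}``.  An observation always carries at
    least one organ (empty draws are rejected and redrawn).
    """
    spec.validate()
    sizes = class_sizes(spec)
    observations = []
    obs_id = 0
    for c in range(spec.n_classes):
        gates = {o: rng.random() < spec.organ_class_gate[o] for o in ORGANS}
        if not any(gates.values()):
            gates["flower"] = True  # a class must have some organ
        for _ in range(int(sizes[c])):
            for _attempt in range(1000):
                present = [o for o in ORGANS
                           if gates[o] and rng.random() < spec.organ_avail[o]]
                if present:
                    break
            else:  # pragma: no cover - probability ~0 unless all avail ~ 0
                present = [o for o in ORGANS if gates[o]][:1]
            counts = {o: 1 + int(rng.poisson(spec.images_per_organ_lambda))
                      for o in present}
            observations.append({
                "observation_id": f"obs{obs_id:06d}",
                "class_id": c,
                "organ_counts": counts,
            })
            obs_id += 1
    return observations


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(spec: SyntheticSpec, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Generate images + metadata under ``out_dir``; returns the metadata table.

    Writes ``images/*.jpg``, ``metadata.csv`` (columns observation_id,
    class_id, organ, image_path) and ``manifest.json``.  Fully deterministic
    given ``spec.seed``: structure and rendering use independent substreams of
    one root seed.
    """
    spec.validate()
    out_dir = str(out_dir)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)

    ss = np.random.SeedSequence(spec.seed)
    structure_rng, render_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    observations = sample_structure(spec, structure_rng)

    rows = []
    for obs in observations:
        for organ in ORGANS:
            n = obs["organ_counts"].get(organ, 0)
            for k in range(n):
                fname = f"{obs['observation_id']}_{organ}_{k}.jpg"
                arr = render_organ_image(
                    obs["class_id"], organ, render_rng,
                    n_classes=spec.n_classes, size=spec.image_size,
                    hue_jitter=spec.hue_jitter[organ],
                    pixel_noise=spec.pixel_noise)
                Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(
                    os.path.join(img_dir, fname), format="JPEG", quality=95)
                rows.append((obs["observation_id"], obs["class_id"], organ,
                             os.path.join("images", fname)))

    meta = pd.DataFrame(rows, columns=["observation_id", "class_id", "organ",
                                       "image_path"])
    meta.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)

    manifest = {
        "seed": spec.seed,
        "n_classes": spec.n_classes,
        "n_observations": len(observations),
        "n_images": len(meta),
        "image_size": spec.image_size,
        "organ_counts": {o: int((meta["organ"] == o).sum()) for o in ORGANS},
        "spec": {
            "class_size_tail": spec.class_size_tail,
            "organ_avail": spec.organ_avail,
            "organ_class_gate": spec.organ_class_gate,
            "images_per_organ_lambda": spec.images_per_organ_lambda,
            "max_observations": spec.max_observations,
            "min_observations": spec.min_observations,
            "pixel_noise": spec.pixel_noise,
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return meta
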