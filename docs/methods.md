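# Methods

This note documents the models, defaults, numerical choices and limitations of
`plantfuse`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from outside the package.

## Problem setting

The input is an observation-grouped collection of plant-organ images: each
observation is one physical specimen of a species, carrying an arbitrary
number of photographs tagged flower / leaf / fruit / stem. The goal is a
classifier that consumes one image per organ (with organs possibly missing)
and predicts the species. Three properties of real collections drive the
design: class sizes are long-tailed, organ availability is skewed
(flower > leaf > fruit > stem), and many species lack whole organs.

## Dataset construction

**Filtering.** Within a class, an organ with fewer than 3 images cannot be
represented in all three splits, so its images are dropped; observations left
empty are dropped; classes with fewer than 3 observations (the unit of
splitting) are dropped.

**Split optimisation.** Splitting must be by observation to avoid leakage,
yet balanced in both observation counts and per-organ image counts. Per
class, we minimise
`sum_s (|x_s| - lambda_s N)^2 + sum_o sum_s (c_o . x_s - lambda_s |c_o|)^2`
over one-hot assignments of observations to splits, lambda = (0.6, 0.2, 0.2).
The solver is exhaustive (vectorised enumeration of all 3^N assignments,
first-minimum = lexicographically smallest optimum) for N <= 12, and
otherwise a deterministic greedy construction (heaviest observations first,
best marginal split) refined by single-observation relocation passes until a
full pass yields no improvement (capped at 200 passes). Exhaustive where
testable, reproducible everywhere: the acceptance suite verifies exact
agreement with a brute-force oracle on 100 random instances with N <= 8.

**Repair.** If a split ends with zero images of an organ the class does have,
one image is moved from the split holding the most images of that organ (ties
resolved train-first). With at least 3 images per organ this always
terminates with every split non-empty; with fewer, repair is best-effort and
logged.

**Multimodal records.** Per class and split, N = max over organs of the image
count. Each present organ's list is permuted once and tiled cyclically to
length N, so each image is used floor(N/n) or ceil(N/n) times; organs absent
from the class contribute no key. Records are shuffled after concatenating
classes (the alternative — shuffling within classes before concatenation —
would leave the loader order class-blocked).

**Export.** Images are converted to RGB, bilinearly resized to a square
(default 256 for full-scale backbones; 32 throughout the tests, since the
tiny backbones have no fixed input requirement), JPEG-encoded at quality 95,
and labels remapped to a contiguous [0, C-1]. Loaders normalise pixels to
[-1, 1].

## Backbones

The default backbone is a deliberately small 3-block CNN (stride-2 3x3
convolutions of widths 8/16/32, ReLU), global average pooling, an
intermediate dense layer (width 32, batch-normalised) and a softmax
classifier. It declares 4 fusible layers: the pooled outputs of the three
conv blocks and the intermediate activation. Any object exposing an ordered
`fusible_layers` list and `fusible_features` works as a backbone; large
pretrained networks would slot in the same way but are outside desk scale.

Unimodal training: Adam, initial LR 1e-3 with continuous exponential decay
(`lr * rate^(step/steps)`, rate 0.95 per 200 steps — the continuous exponent
matches a staircase at multiples of 200 and is smoother between; a staircase
flag exists), batch 32, early stopping on validation loss (patience 10 by
default) with best-weights restoration, per-epoch shuffling, and per-organ
augmentations (horizontal flip everywhere; vertical flip for leaves, whose
orientation is arbitrary; contrast scaling (c - mu)k + mu with k ~ U(0.75,
1.25) for the colour-dominated flower and fruit). Each enabled augmentation
is applied independently with probability 0.5 (a rate had to be chosen; 0.5
keeps the clean image frequent). An optional transfer-learning mode freezes
the conv base and trains only the appended layers, with a fine-tuning phase
that unfreezes the base at a lower LR and suppresses early stopping before a
configurable epoch.

**Class weighting.** All losses are weighted cross-entropy with
w_c = N / (|C| * N_c); the identity sum_c N_c w_c = N holds exactly and is
property-tested. Probabilities at the true class are clipped at 1e-7.

## Fusion architecture search

Configurations, construction and the search loop follow the scheme described
in the README. Implementation-specific choices:

- **Feature caching.** Backbones are frozen during search and final training,
  so every record's pooled features at each fusible layer are computed once;
  candidate training is then dense-only. A record missing an organ carries
  that backbone's features of an all-zero input — byte-identical to what
  multimodal dropout substitutes, so the missing-modality and dropped-modality
  paths coincide (tested).
- **Surrogate.** Zero-masked embedding (dim 100), LSTM (100 units), single
  sigmoid output; Adam at 1e-3, MSE, 50 epochs, batch 64; refit each level on
  the entire result set. Tokens are 1 + the flat offset of (modality, layer)
  or of the activation, per position; 0 is padding; sequences are right-padded
  to L(m+1). Known results override surrogate predictions when ranking
  candidates.
- **Sampling.** Scores a_i are normalised to p_i = a_i / sum a_j and drawn
  without replacement with per-draw weights p_i^(1/t), renormalised after
  each draw; computed in log space. Temperature schedule defaults
  t_max = 10, t_min = 0.2, d = 4. All-zero scores fall back to uniform with a
  warning.
- **Progression.** The sampled set is extended at level l by appending a
  layer to shorter members and replacing the l-th layer of members already at
  length l; candidate pools are deduplicated preserving order. After the
  exhaustive first level, the progression continues from a temperature-sampled
  subset of the singles.
- **Weight sharing.** The store key is (layer position, weight shape,
  activation index) — including the activation, since the same matrix behaves
  very differently under ReLU and sigmoid. The classifier head is shared by
  shape. Candidates initialise from the store and write back after training.
- **Checkpointing.** Results and the sampled set are JSON; surrogate weights
  an `.npz` beside it. A restarted search skips completed levels.

Search-time candidate training: 2 epochs, fusion width 64, Adam 1e-3,
class-weighted loss, cached batches shuffled in buffers of 12 (a fixed batch
partition whose order is permuted within consecutive windows of 12 each
epoch — randomness at a fraction of the shuffling cost).

## Final training and multimodal dropout

The best configuration is retrained with batch normalisation after each
fusion layer, Adam at 5e-4 (decay 0.9 per 200 steps), early stopping on
validation macro F1 (the selection metric of the search) with best-weights
restoration. Two variants are produced: without multimodal dropout and with
it at rate 0.125 — each present modality of a sample is zeroed independently,
so a sample may lose all modalities (the independent-draws reading; the
alternative of protecting one modality was rejected as it changes the
per-modality marginal rate). Dropout draws come from a dedicated substream,
so the two variants see identical batch orders.

## Evaluation

Macro metrics average per-class values uniformly; macro F1 is the mean of
per-class F1 (not the harmonic mean of macro precision and macro recall —
the two differ). Per-class ratios with zero denominators score 0 and are
counted in the report. Top-N uses a stable sort by (-probability, class
index). McNemar's test is the continuity-corrected chi-square
(|b-c|-1)^2/(b+c) on the discordant counts, 1 df, with an exact binomial
option for small b + c; b + c = 0 is flagged degenerate with p = 1. Subset
evaluation keeps only records possessing every organ of the subset, feeds the
fusion model zero-features for organs outside it, and restricts the
late-fusion average to the subset's unimodal models.

## Synthetic data

The generator emulates the structure that matters to the pipeline, not
photographic realism. Class sizes follow a truncated Zipf profile (exponent
0.7, largest class 30 observations by default). Each organ has a
per-observation availability (0.90 / 0.75 / 0.55 / 0.40) and a class-level
gate (1.0 / 0.95 / 0.85 / 0.75) under which a class lacks the organ entirely;
observations are redrawn until non-empty. Image counts per present organ are
1 + Poisson(0.6). Rendering: the class fixes a hue on the colour circle and a
stripe frequency; the organ fixes a shape template (petalled disc, rotated
ellipse, paired discs, curved bar) and a hue-jitter level (0.22 / 0.35 /
0.55 / 0.85 radians) that makes flowers the most reliable cue and stems the
least, plus Gaussian pixel noise (sd 0.06). One root seed is split into
independent substreams for structure and rendering; generation is
byte-identical across runs.

What passing tests therefore show: the pipeline's mechanics, determinism and
the qualitative orderings (fusion beats unimodal and late fusion; multimodal
dropout trades full-modality accuracy for missing-modality robustness) hold
under a faithful structural model of multi-organ data. What they do not show:
absolute accuracies on real photographs, which depend on image statistics and
backbone capacity far beyond the synthetic renderer and the tiny CNNs.

## Problem sizes and defaults

The packaged study runs 10 classes, 32x32 images, ~120 observations, a
2-iteration x 2-level search sampling 12 architectures per step over
4 fusible layers x 4 organs x 2 activations (512 single-layer
configurations), and 60-epoch final training — chosen so a complete study,
including the exhaustive first level, finishes in well under a minute on one
CPU core. The schedule accounting (`count_schedule`) reproduces the
full-scale arithmetic exactly: 2592 single-layer configurations,
2592 + 50 x 19 = 3542 unique architectures, (2592/20 + 950) x 2 = 2159.2
per-worker epoch-equivalents, 7084 sequential.

## Known limitations

- The numpy engine is single-threaded and desk-scale by design; it is not a
  general training framework.
- The search's candidate pool at level l is the full cross product of the
  sampled set with the single-layer pool; at very large pool sizes the
  surrogate ranking pass, not candidate training, dominates.
- The late-fusion baseline uses uncalibrated softmax averages; probability
  calibration is out of scope.
- The split heuristic above N = 12 is locally optimal only; no optimality gap
  is reported.
- Multimodal dropout may zero every modality of a sample; with rate 0.125 and
  four organs this affects ~0.02% of samples per epoch and is harmless, but
  rates near 1 degenerate.
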