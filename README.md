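# plantfuse

Automatic multimodal fusion for plant identification from organ images.

Plant species are far easier to recognise from several organs at once — a
flower, a leaf, a fruit, a stem — than from any single photograph, but real
collections are observation-grouped (one specimen, arbitrarily many photos),
long-tailed in class size, and riddled with missing organs. `plantfuse`
implements the full pipeline that turns such a collection into a fixed-input
multimodal classifier:

1. **Dataset construction.** Images are grouped by observation, rare organs
   and classes are filtered, and observations are assigned to
   train/validation/test splits by solving, per class, the constrained binary
   program

   minimise  Σ_s (‖x_s‖₁ − λ_s N)² + Σ_o Σ_s (c_oᵀ x_s − λ_s ‖c_o‖₁)²
   subject to Σ_s x_s = 1,

   which balances both observation counts and per-organ image counts against
   the target fractions λ = (0.6, 0.2, 0.2). Empty organ splits are repaired
   by transferring single images from the largest split. Each class then
   yields N = max(n_flower, n_leaf, n_fruit, n_stem) multimodal records by
   permuting and cyclically tiling each organ's images; absent organs are
   omitted from the record.

2. **Fusion architecture search (MFAS).** Each organ has a frozen
   pre-trained backbone exposing n_i fusible layers. A fusion network is
   described by tuples γ_l = (γ_l¹, …, γ_lᵐ, γ_lᵃ): which layer of each
   backbone to tap and which activation to use in fusion layer
   h_l = σ_{γ_lᵃ}(W_l [x_{γ_l¹}⁽¹⁾; …; x_{γ_lᵐ}⁽ᵐ⁾; h_{l−1}]).
   The search space of size (n₁ × ⋯ × n_m × k)^L is explored progressively:
   the single-layer level exhaustively, then each level samples architectures
   by temperature sampling (p_i^{1/t}/Σ_j p_j^{1/t}, with
   t(s) = (t_max − t_min)e^{−(s/d)²} + t_min) over scores predicted by an
   LSTM surrogate trained on all results so far. Fusion weights are shared
   across configurations through a store keyed by layer position, weight
   shape and activation; revisited configurations keep their best score.

3. **Training.** All models use the class-weighted cross-entropy with
   w_c = N/(|C|·N_c) against the long tail, Adam with an exponentially
   decaying learning rate, per-organ image augmentations, and cached batches
   shuffled in buffers of 12. The final fusion model is trained twice: with
   and without **multimodal dropout** (each present organ image zeroed with
   probability 0.125), which trades a little full-modality accuracy for
   robustness when organs are missing.

4. **Evaluation.** Accuracy, macro precision/recall/F1 and top-N accuracy;
   a late-fusion baseline ĉ = argmax_c (1/|M_x|) Σ_m p_m(c|x) over the
   available unimodal models; McNemar's test (continuity-corrected) for
   paired comparisons; and per-modality-subset evaluation that feeds the
   fusion model zeros for organs outside the subset.

A seeded synthetic generator reproduces the statistical shape of real
multi-organ collections (long-tailed classes, organ-availability skew
flower > leaf > fruit > stem, classes lacking whole organs, per-organ cue
reliability), so the entire pipeline runs and is tested end-to-end with no
downloads. All neural components (tiny CNN backbones, fusion heads, the LSTM
surrogate) run on a compact numpy engine included in the package.

## Worked example

```bash
plantfuse run-study --workdir study --seed 1
```

runs the complete pipeline on synthetic data (10 classes, 32×32 images,
~120 observations; search over 4 fusible layers × 4 organs × 2 activations)
in under a minute on one CPU core and prints the summary:

```json
{
  "multimodal_f1": 0.9289,
  "multimodal_md_f1": 0.7743,
  "baseline_f1": 0.9127,
  "best_unimodal_f1": 0.8706,
  "beats_all_unimodal": true,
  "beats_baseline": true,
  "single_subset_mean_md": 0.1582,
  "single_subset_mean_no_md": 0.0362,
  "md_wins_single_subsets": true,
  "no_md_wins_full_subset": true
}
```

Reading: the searched fusion model (macro F1 0.93 on the multimodal test
split) beats the best unimodal model (flower, 0.87) and the late-fusion
baseline (0.91). The variant trained with multimodal dropout is far more
robust when only a single organ is available (mean single-organ F1 0.16 vs
0.04) but cedes the full-modality case to the variant trained without it —
the characteristic trade-off of multimodal dropout.

Library use mirrors the CLI: `plantfuse.synthetic.generate_dataset` →
`plantfuse.dataset.build_dataset` → `plantfuse.pipeline.run_study`, or call
the individual stages (`train_unimodal`, `run_search`, `train_multimodal`,
`evaluate_modality_subsets`) directly.

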