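# Methods

## Model

The classifier treats PPI prediction as comparative density estimation:
one autoencoder per class learns to reconstruct the feature vectors of its
own class, and a pair is assigned to the class whose autoencoder reconstructs
it better. With L⁺ and L⁻ the per-pair mean squared reconstruction errors,

    pr⁻ = 0.5 + (L⁺ − L⁻) / (2(L⁺ + L⁻)),   pr⁺ = 1 − pr⁻,

which is bounded in [0, 1], sums to 1 with pr⁺, equals 1 when L⁻ = 0 (< L⁺)
and is invariant to rescaling both losses. The decision rule is strict:
interacting iff L⁺ < L⁻; ties — including the degenerate 0/0 case at
L⁺ = L⁻ = 0, which symmetry resolves to pr = 0.5 — are called
non-interacting. (Some descriptions of this rule state the inequality with
the opposite sign next to the formula; the formula itself fixes the
direction used here, and the tie-to-negative convention follows the strict
"interact iff L⁺ < L⁻" reading.)

## Features

**CT.** Residues map to 7 classes — the Shen grouping {A,G,V}, {I,L,F,P},
{Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}, overridable via
`DescriptorConfig.class_map`. Triple (c1,c2,c3) is linearized c1-major:
index = (c1−1)·49 + (c2−1)·7 + (c3−1). Two normalizations are provided:
`minmax` (default, (f − min f)/max f per protein, matching the common
iFeature convention) and `relative_frequency` (f/(L−2), values sum to 1).
Sequences shorter than 3 residues are rejected.

**AC.** Property scales are standardized to zero mean / unit variance over
the 20 residues (population std, ddof 0) before use; the per-sequence mean
P̄ⱼ is subtracted inside the sum and each term is scaled by 1/(L−d). Output
is property-major, then lag. `lag` must be strictly smaller than the cleaned
sequence length; violations raise an actionable error naming the protein
rather than being silently skipped.

**Property table.** The 14 bundled scales are the canonical published ones
matching their names (Kyte–Doolittle and Fauchère–Pliška hydrophobicity,
Hopp–Woods hydrophilicity, side-chain net charge index, Grantham and
Zimmerman polarity, Charton polarizability, solvent-accessible surface area,
side-chain volume, Bhaskaran–Ponnuswamy flexibility, Janin accessibility,
Chothia exposed surface, Chou–Fasman turn propensity, Welling antigenic
propensity). The table is data, not code: any m×20 table loads via
`load_property_table`, and correctness of AC values is defined relative to
the supplied table.

**Order.** Per protein, AC precedes CT in the concatenation; a pair is
[features(p) | features(p′)] in file order (pairs are ordered; no
symmetrization is applied, matching the concatenation definition).
Every `FeatureVector` carries a fingerprint of its `DescriptorConfig`;
mixing fingerprints in a pair, or predicting with a model trained under a
different config, is an error.

## Architectures and training

All encoders use two SELU layers of 600 linked to a SELU bottleneck of 300;
decoders mirror the hidden widths (600, 600) with a linear output layer
sized to the reconstruction target. Output activation is linear because AC
features are signed. Weights are LeCun-normal (the standard companion of
SELU), seeded.

* **joint_joint**: 2k → 600 → 600 → 300 → 600 → 600 → 2k.
* **siamese_joint**: shared encoder k → 600 → 600 → 300 applied to both
  proteins; decoder on [z | z′] (width 600) → 600 → 600 → 2k. The decoder
  reconstructs the 2k pair directly from the 600-wide concatenation rather
  than re-expanding through a 300-wide stage; this is the minimal reading of
  "symmetric" for this variant and is pinned for reproducibility.
* **siamese_siamese**: shared encoder as above; ẑ = z ⊙ z′; a shared decoder
  maps [z | ẑ] → p̂ and [z′ | ẑ] → p̂′ (each 600 → 600 → 600 → k). The total
  loss is the mean of the two per-protein MSEs, which makes this variant
  exactly swap-invariant; the joint variants are not.

Training: Adam (β₁ 0.9, β₂ 0.999), initial learning rate 5·10⁻⁴, batch 64,
2000 epochs by default; a seeded 10% validation split drives a plateau
schedule that halves the learning rate after 5 epochs without strictly lower
validation loss, floored at 10⁻⁵. "Improvement" uses no minimum delta.
Final-epoch weights are returned; best-validation checkpointing is available
behind `TrainingConfig.checkpoint_best` (default off). The implementation is
float32 NumPy with hand-written backpropagation (verified against numerical
gradients during development); runs are bit-reproducible for a fixed seed.

`DESK_SCALE` (epochs = 50, all other settings and the full layer widths
unchanged) is the preset used by the test suite's end-to-end experiment;
layer widths are additionally overridable for tiny-feature unit tests.

## Evaluation

Metrics are the standard confusion-matrix formulas with "positive" =
interacting. The headline ranking metric is balanced accuracy,
(specificity + recall)/2, named `auc_balanced`; a conventional rank-based
ROC-AUC over pr⁺ scores exists as a diagnostic (`rank_roc_auc`) and is never
reported as part of `MetricsReport`. Degenerate denominators (e.g. no
predicted positives) yield 0 with a logged warning rather than NaN.

Cross-validation shuffles and partitions each class independently into k
seeded folds (training is per-class by construction, so per-class
stratification is the natural choice); fold i is tested after fitting a
fresh (AE⁺, AE⁻) pair on the other k−1 folds. The 95% CI is the Student-t
interval on per-fold values, t₀.₉₇₅,ₙ₋₁ · s/√n with s the sample standard
deviation (ddof 1) — the standard small-n interval for k ≤ 10 folds.

## Synthetic benchmark

The generator emulates a two-class pair benchmark: variable-length sequences
(default 50–250 residues, uniform) over the 20-letter alphabet with a
uniform residue background (a skewed, roughly database-like composition is
available as `SKEWED_BACKGROUND` to stress normalization). The planted
signal is **complementary interface motifs**: the proteome splits into an
A pool, a B pool and a background pool; each pool protein receives, with
probability `signal_strength`, 3 copies of its motif (5-mers over rare
residues W/C/M, so chance occurrences are negligible). Positive pairs couple
an A-pool with a B-pool protein; negative pairs are drawn within the
background pool, so no negative carries coordinated motifs. Repeated short
linear motifs perturb the CT channel directly and AC weakly — the signal
path the autoencoders are meant to pick up. At `signal_strength = 0` nothing
is planted and the classes are exchangeable.

What this does **not** emulate: real PPI network topology (hubs, degree
distributions), homology structure between sequences, localization-based
negative sampling, or realistic class overlap — real benchmarks show far
less separable classes. Passing tests therefore demonstrate that the
pipeline is implemented correctly and can recover a compositional signal
end-to-end, not that it attains any particular accuracy on real data.

## Problem sizes

The end-to-end experiment in the test suite uses 400 proteins,
1000 + 1000 pairs, full signal strength, lag 5 with 3 property scales
(k = 358), 5-fold cross-validation, and the `DESK_SCALE` preset for both the
siamese–siamese and joint–joint variants — about five minutes of single-core
compute, chosen so the whole suite runs comfortably on a laptop. Unit tests
use narrowed layer widths (e.g. 8–16 neurons) where the property under test
does not depend on capacity.

## Known limitations

* No early stopping; long runs rely on the plateau schedule alone.
* The probability formula is used as defined, uncalibrated; pr⁺ is a
  monotone transform of the loss gap, not an empirical frequency.
* Pairs are ordered; a user wanting orientation-invariant predictions with
  the joint variants should average over both orientations themselves (the
  siamese–siamese variant is invariant by construction).
* The bundled property values are the canonical published scales matching
  the 14 names; substituting another table changes AC features and hence any
  trained model's fingerprint.
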