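# autoppi

Sequence-based prediction of protein–protein interactions (PPI) with a pair
of class-specific autoencoders.

## The problem and the approach

Given only the primary sequences of two proteins *p* and *p′*, decide whether
they physically interact. Each protein is mapped to a fixed-length vector of
**k = 343 + m·lag** features:

* **Conjoint Triad (CT)** — the 20 amino acids are grouped into 7
  physicochemical classes (Shen grouping); a window of size 3 slides over the
  sequence and the normalized frequencies of the 7³ = 343 ordered class
  triples are recorded.
* **Autocovariance (AC)** — for each of *m* amino-acid property scales
  (standardized over the 20 residues) and each offset *d* = 1..lag,

  AC(j, d) = (1/(L−d)) · Σᵢ (Pⱼ(aᵢ) − P̄ⱼ)(Pⱼ(aᵢ₊d) − P̄ⱼ),

  capturing longer-range compositional structure. The bundled default table
  carries 14 named scales (hydrophobicity ×2, hydrophilicity, net charge
  index, polarity ×2, polarizability, solvent-accessible surface area,
  side-chain volume, flexibility, accessibility, exposed surface, turn
  propensity, antigenic propensity).

A pair is the 2k concatenation of the two protein vectors. Two autoencoders
are trained: **AE⁺** only on interacting pairs and **AE⁻** only on
non-interacting ones (three architectures: joint–joint, siamese–joint,
siamese–siamese; SELU layers 600–600–300 with a mirrored decoder; Adam,
MSE loss, halve-on-plateau learning rate). A new pair is scored by both; with
L⁺ and L⁻ the per-pair reconstruction errors,

    pr⁻(p, p′) = 0.5 + (L⁺ − L⁻) / (2 · (L⁺ + L⁻)),     pr⁺ = 1 − pr⁻,

and the pair is called interacting exactly when L⁺ < L⁻. Evaluation is
k-fold cross-validation (per-class folds) reporting accuracy, precision,
recall, specificity, F1 and balanced accuracy (`auc_balanced` =
(specificity + recall)/2) with 95% Student-t confidence intervals.

## Worked example

A synthetic benchmark with planted complementary interface motifs (see
`autoppi.synthetic_data`) exercises the full pipeline without downloads:

```python
from autoppi import (SynthesisConfig, generate_dataset, DescriptorConfig,
                     default_property_table, cross_validate, desk_scale_config)

scfg = SynthesisConfig(n_proteins=120, n_pos=200, n_neg=200,
                       signal_strength=1.0, lag=5, seed=7)
proteome, pairs = generate_dataset(scfg)
dcfg = DescriptorConfig(lag=5, property_table=default_property_table().iloc[:3])
print(f"k = {dcfg.k} features per protein")
report = cross_validate(proteome, pairs, k=5, arch="siamese_siamese",
                        tconfig=desk_scale_config(seed=7), dconfig=dcfg, seed=7)
print(report.summary())
```

prints

```
k = 358 features per protein
accuracy: 1.0000 ± 0.0000
precision: 1.0000 ± 0.0000
recall: 1.0000 ± 0.0000
specificity: 1.0000 ± 0.0000
f1: 1.0000 ± 0.0000
auc_balanced: 1.0000 ± 0.0000
```

— with full signal strength the planted motif co-occurrence is perfectly
separable, so every fold classifies every held-out pair correctly (each line
is the fold mean ± the 95% CI half-width). A single-pair prediction looks
like:

```
SYN00007 x SYN00043: L+ = 0.0049, L- = 0.0876, pr+ = 0.947, interacting = True
```

i.e. the positive-class autoencoder reconstructs this pair ~18× better than
the negative-class one, so the pair is called interacting with pr⁺ ≈ 0.95.

## Command line

```sh
autoppi simulate  -o data --n-proteins 200 --seed 1        # FASTA + pair TSV
autoppi featurize data/proteins.fasta -o features.tsv
autoppi train     data/proteins.fasta data/pairs.tsv -o model --arch siamese_siamese
autoppi predict   model data/proteins.fasta data/pairs.tsv -o predictions.tsv
autoppi evaluate  data/proteins.fasta data/pairs.tsv -o cv_report --k 5
```

All commands accept `--config run.yaml` (flags override the file) and a
single `--seed` that fans out to every random component.

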