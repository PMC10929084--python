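# rpifusion

Multi-feature prediction of lncRNA–protein interactions (RPI).

Long non-coding RNAs act through physical association with RNA-binding
proteins, and testing candidate pairs experimentally is slow and costly.
`rpifusion` is a complete, testable implementation of a multi-source RPI
classifier for computational biologists: given RNA and protein sequences,
their secondary structures, and a protein–protein interaction (PPI)
network, it predicts for any (RNA, protein) pair whether the two interact.

## Method

Each candidate pair is described by four feature families:

1. **Sequence (739 dims).** RNA: stacked k-mer frequencies for
   k = 1..4 (4 + 16 + 64 + 256 = 340 dims), each sub-block a probability
   distribution over the L − k + 1 windows. Protein: residues are mapped to
   the seven conjoint-triad groups {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
   {R,K}, {D,E}, {C} and group k-mer frequencies for k = 1..3 are stacked
   (7 + 49 + 343 = 399 dims).
2. **Secondary structure (40 dims).** Dot-bracket (RNA) and C/E/H
   (protein) strings are digitized (·→0, bracket→1; C→0, E→1, H→2) and
   compressed to 20 signed coefficients each by the half-sample-shifted
   cosine series
   `X_i = √(2/l) Σ_{n=0}^{l−1} x_n cos[(π/l)(n+½)(i+½)]`, i = 0..19,
   making vectors of heterogeneous lengths comparable.
3. **Physicochemical (25 dims).** 22 lag-1 auto-covariances of z-normalized
   dinucleotide properties along the RNA, plus 3 first-tier sequence-order
   correlation factors (hydrophobicity, hydrophilicity, mass) for the
   protein.
4. **PPI (100 dims).** A symmetric score matrix (unit diagonal, reference
   set capped at the 400 highest-degree proteins) is reduced by PCA; each
   protein contributes its 100-dim projected row, or zeros when absent
   from the network.

A random forest ranks every feature by its total Gini-impurity decrease
(VIM = Σ_trees Σ_nodes ΔGini), and each block independently keeps its top
80% (configurable; floor(q·d) features). The retained blocks feed a
parallel convolutional network — per block, three kernel-3 1-D
convolutions in two pooled stages with ReLU→BatchNorm ordering — whose
flattened branch outputs are fused by concatenation (or stacking with a
logistic second stage) into fully connected layers of 16, 8 and 2 units
with softmax; a pair is called interacting when P(interaction) > 0.5.
Evaluation reports ACC, SEN, SPE, PRE, F1, MCC and the rank (Mann–Whitney)
AUC under stratified five-fold cross-validation, with selection refit on
training folds only.

A synthetic-data module generates all four input kinds with a planted
rule — a pair interacts iff its RNA and protein both carry fixed sequence
motifs — so the whole pipeline is testable end-to-end without external
databases.

## Worked example

```python
import numpy as np
import rpifusion as rf
from rpifusion.classifier import ModelConfig, build_model, train
from rpifusion.selection import fit_selection_masks
from rpifusion.evaluate import rank_auc

cfg = rf.SimulationConfig(n_rna=60, n_protein=60, n_positive=150,
                          rna_length_range=(80, 200),
                          protein_length_range=(60, 150), seed=42)
ds, pairs = rf.simulate_labeled_dataset(cfg)
blocks, labels = rf.encode_dataset(
    pairs, ds.rnas, ds.proteins,
    ds.rna_structures, ds.protein_structures, ds.ppi_edges)
print({k: v.shape for k, v in blocks.items()})

rng = np.random.default_rng(42)
idx = rng.permutation(labels.size)
tr, te = idx[:240], idx[240:]
masks = fit_selection_masks({k: v[tr] for k, v in blocks.items()},
                            labels[tr], retain_fractions=0.8,
                            n_trees=300, seed=42)
print({k: m.n_kept for k, m in masks.items()})

mcfg = ModelConfig(seed=42)
model = build_model(mcfg, {k: m.n_kept for k, m in masks.items()})
train(model, {k: m.apply(blocks[k][tr]) for k, m in masks.items()},
      labels[tr], mcfg)
probs = model.predict_proba(
    {k: m.apply(blocks[k][te]) for k, m in masks.items()})
acc = ((probs[:, 1] > 0.5) == labels[te]).mean()
print(f"held-out ACC {acc:.3f}  AUC {rank_auc(probs[:, 1], labels[te]):.3f}")
```

prints

```
{'sequence': (300, 739), 'structure': (300, 40), 'physchem': (300, 25), 'ppi': (300, 100)}
{'sequence': 591, 'structure': 32, 'physchem': 20, 'ppi': 80}
held-out ACC 0.983  AUC 1.000
```

The block shapes show the four encoder dimensionalities; the mask counts
show 80% retention (739→591, 40→32, 25→20, and 80 of the 100 PPI
dimensions — the matrix rank caps the non-zero PCA axes at the number of
proteins, here 60, before padding). The final line is held-out
performance on 60 unseen pairs: the planted motif rule is recovered
almost perfectly.

The same pipeline is available from the shell:

```sh
rpifusion simulate --seed 5 --outdir data/
rpifusion encode   --datadir data/ --outdir features/
rpifusion select   --featuredir features/ --outdir masks/
rpifusion train    --featuredir features/ --maskdir masks/ --outdir model/
rpifusion evaluate --featuredir features/ --outdir eval/   # five-fold CV
rpifusion predict  --model model/model.npz --featuredir features/ \
                   --maskdir masks/ --outdir preds/
```

`evaluate` writes a per-fold + mean metric table (`metrics.tsv`); every
artifact embeds the digest of the config that produced it, and `predict`
refuses a model/feature digest mismatch.

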