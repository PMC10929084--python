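# Methods

This note documents the models and procedures implemented in `rpifusion`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

The package predicts a binary label — interacting / non-interacting — for
(lncRNA, protein) pairs from four information sources: primary sequence,
secondary structure, physicochemical profile, and the protein's position
in a PPI network. Real training corpora pair experimentally confirmed
interactions with negatives sampled uniformly from the unobserved
(RNA, protein) combinations, in equal number; the synthetic generator
reproduces that protocol.

## Feature encoders

**Stacked k-mer (RNA) and conjoint triad (protein).** Frequencies of all
k-mers for k = 1..4 over A<C<G<U (340 dims) and of 7-group k-mers for
k = 1..3 over groups 1..7 (399 dims). Two conventions the raw definition
leaves open are fixed here: the denominator of each sub-block is the
window count L − k + 1, so every sub-block is a probability distribution;
and sequences shorter than k contribute an all-zero sub-block rather than
an error, since real corpora contain heterogeneous lengths. Index order
within a sub-block is lexicographic and stable across runs. Selenocysteine
(U) is accepted in protein input and treated as cysteine.

**Cosine-series structure compression.** Structure strings are digitized
(unpaired 0 / paired 1 for RNA; coil 0, sheet 1, helix 2 for protein) and
compressed to the first 20 coefficients of the half-sample-shifted cosine
series with √(2/l) scaling — the orthonormal type-IV DCT prefix when
l ≥ 20 (cross-checked against `scipy.fft.dct(type=4, norm="ortho")` in the
tests). Coefficients are kept signed; magnitudes would discard the phase
information that distinguishes, e.g., a 5'-paired from a 3'-paired
molecule, and the shift-sensitivity test guards exactly that. Series
shorter than 20 still yield 20 coefficients (the kernel is defined for
any frequency index); the input is never zero-padded. When several
suboptimal structures are supplied for one molecule, encoded vectors are
averaged after the transform, so alternatives of unequal length combine
cleanly; the prediction is insensitive to how many suboptimal structures
are supplied.

**Reduced physicochemical descriptors.** One scalar per property: the
lag-1 auto-covariance of z-normalized dinucleotide property values along
the RNA (22 properties), and the first-tier sequence-order correlation
factor — mean squared difference of adjacent normalized residue values —
for the protein (hydrophobicity, hydrophilicity, mass). This is the
minimal sequence-order-aware reduction consistent with the 22 + 3 = 25
output dimensions; full auto-cross-covariance lag spectra are out of
scope. Property values are z-normalized across their 16 (or 20) units
before encoding, which makes the descriptors invariant to the units of
the raw scales; a constant property is rejected as degenerate. The
bundled default tables combine exactly computable content fractions
(adenine/GC/purine/keto/cytosine/thymine/guanine content per
dinucleotide, with U read as T for the thymine column) with published
A-form helix step geometry, nearest-neighbour thermodynamics, dinucleotide
hydrophilicity scales, and the Kyte–Doolittle, Hopp–Woods and residue-mass
scales for proteins. The "… 1" property pairs are alternative published
scales and are kept as distinct columns. Any table with the same layout
can be substituted via TSV; only the dimensionality is structural.

**PPI projection.** The symmetric score matrix (unit diagonal, missing
entries 0) is built over a reference set capped at 400 proteins — chosen
by descending degree, ties broken by id, since some criterion is needed
and degree keeps the best-connected (most informative) rows. Rows are
mean-centered and PCA-projected to 100 dimensions; ranks below 100 are
zero-padded. The per-axis sign ambiguity of PCA is fixed by making each
axis's largest-magnitude loading positive, so identical inputs give
bit-identical projections. Each sample's PPI feature is the 100-vector of
its protein; proteins outside the reference set map to the zero vector
(logged, with the zero-rate reported), which matches how proteins absent
from a PPI database are handled.

## Feature selection

Variable importance is the total Gini-impurity decrease: for each
internal node split on a feature, (w·GI − w_l·GI_l − w_r·GI_r) with
GI = 1 − Σ p_k² and w the fraction of training samples reaching the node,
summed over all nodes of all trees and normalized once to sum to 1. The
forest is scikit-learn's; the importance extraction deliberately sums the
raw per-tree decreases rather than using the library's per-tree-normalized
`feature_importances_`, and a from-scratch re-derivation over the tree
structure cross-checks the extraction in the tests. Each block keeps its
floor(q·d) highest-importance features (q = 0.8 default: 739→591, 40→32,
25→20), ties broken toward the lower original index. Selection is refit
on training folds only inside cross-validation; fitting it once on the
full data would leak test labels into the mask and inflate fold metrics.
Default forest size is 500 trees with an exposed seed.

## Classifier

Each block feeds a 1-D convolutional branch: Conv(k=3) → Conv(k=3) →
ReLU → BatchNorm → MaxPool(2), then Conv(k=3) → ReLU → BatchNorm →
MaxPool(2), then Flatten — three convolutions per branch in two pooled
stages. Kernel length 3 is the 1-D analogue appropriate to these
vector-valued inputs. ReLU is applied before BatchNorm throughout; the
ordering is unconventional but intentional and covered by tests. Branches
whose (post-selection) input is too short for the full stack fall back to
a single Conv → ReLU → BN → Pool stage with a logged warning; inputs
shorter than 4 are rejected. Flattened branch outputs are concatenated
into a fully connected 16 → 8 → 2 head with softmax; a pair is positive
when P(interaction) > 0.5 strictly, so a score of exactly 0.5 is negative.
The alternative stacking fusion trains one single-branch network per
block and combines their predicted probability pairs (4 × 2 meta-features)
with a logistic second stage.

The network is implemented directly on numpy with explicit
forward/backward passes (im2col convolution, standard BatchNorm
gradients, argmax-routed pooling) and Adam (default, lr 1e-3) or
momentum-SGD optimizers. Per-column input standardization is fitted on
the training set and stored with the model; the feature families differ
in scale by orders of magnitude (k-mer frequencies ~1e-2, cosine
coefficients ~1), and branches train poorly without it. Defaults:
16 channels per convolution, pool 2, batch 32, 50 epochs with early
stopping on an internal 10% stratified validation split (patience 10,
best weights restored; disabled automatically when the split would be
smaller than 8 samples). All randomness (initialization, shuffling,
splits) derives from the config seed, so single-threaded CPU runs are
bit-reproducible. Checkpoints serialize weights, BatchNorm running
statistics, normalization constants and the config.

## Evaluation

ACC, SEN, SPE, PRE = TP/(TP+FP), F1, and MCC from the confusion table at
the 0.5 threshold; any metric with a zero denominator is reported as 0
and flagged degenerate rather than erroring, because small CV folds can
produce empty cells. AUC uses the rank formulation
(Σ ranks of positives − |P|(|P|+1)/2) / (|P||N|) with average ranks under
ties — equivalent to the Mann–Whitney statistic and, as the tests assert,
to trapezoidal integration of the empirical ROC to 1e-9. Cross-validation
uses stratified rather than plain random folds; on balanced data the
difference is negligible and stratification protects the degenerate
single-class-fold case. The mean report is the arithmetic mean of fold
metrics. ROC/PR curves come from a threshold sweep over unique scores;
AUPR uses step-wise interpolation.

## Synthetic data

The generator plants a conjunction rule: uniform-composition sequences,
with an 8-nt RNA motif and a 6-aa protein motif overwritten at 2–4 random
positions in carrier molecules (each molecule a carrier with probability
0.5), and a pair interacting iff both molecules contain their motif —
judged by actual containment, so chance occurrences count. Negatives are
sampled uniformly from the combinations that do not satisfy the rule;
sampling them merely outside the positive *list* would mislabel
carrier-carrier pairs and put a ceiling on attainable accuracy. Labels
can optionally be flipped with probability `label_noise` (default 0 — the
default conditions are clean planted signal; noise is an explicit dial).
Carrier proteins form a high-score PPI clique (scores U[0.7, 1]) over a
sparse U[0, 0.3] background (density 0.05), so the PPI channel carries
correlated signal; structure strings (balanced stem-loops for RNA, C/E/H
run-lengths for protein) are deliberately signal-free, which makes
directional ablations possible. Default sizes — 120 RNAs, 120 proteins,
400 positive pairs, RNA 100–300 nt, protein 80–250 aa — keep molecule
reuse across pairs realistic (each molecule appears in several pairs, as
in curated RPI corpora) while a laptop-scale run finishes in about a
minute.

The motif-containment rule concentrates signal in k-mer space, which is
the method's primary channel; it does not emulate binding-site
thermodynamics, realistic base composition, domain structure, or the
length and degree distributions of curated datasets. Passing the
end-to-end recovery tests therefore shows that the pipeline's plumbing,
encoders, selection and optimizer can recover a strong compositional
signal — not that the method attains any particular accuracy on real
benchmark corpora.

## Problem sizes used in the checks

The statistical acceptance checks train on a 400-positive/400-negative
simulation with a 50/50 train/test split (three seeds, median), run a
label-shuffled control of the same size (ACC must stay within 0.5 ± 0.07
over 400 test pairs), and measure informative-feature retention on a
20-informative/80-noise design (200 samples, 20 seeds, 250 trees).
`scripts/acceptance.py` uses a 100-positive simulation over 40 RNAs and
40 proteins with 200-tree forests — the retained-dimension counts it
reports are floor arithmetic and independent of these sizes.

## Known limitations

- The from-scratch network runs on a single CPU thread; it is sized for
  hundreds-to-thousands of pairs, not for GPU-scale corpora.
- Only the random-forest selector is implemented; the selector sits
  behind `fit_selection_masks` so alternatives (LASSO, elastic net, …)
  can be added.
- The PPI feature is per-protein; pairs whose protein lacks network data
  fall back to zeros and lean on the other three families.
- Bundled physicochemical tables are representative published scales, not
  a canonical registry; conclusions that hinge on a specific scale should
  supply their own table.
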