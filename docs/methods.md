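# Methods

## Problem and model

Typed drug–drug interaction (DDI) prediction asks, for an ordered pair of
drugs (a, b), which of a fixed vocabulary of interaction types (e.g.
"increased risk of hypoglycemia") the pair exhibits. The package represents
each drug by a 977-dimensional transcriptome signature — differential
expression of landmark genes versus control, in the style of replicate-
collapsed L1000 level-5 signatures — and by a 1024-bit Morgan (circular)
fingerprint of its chemical structure.

The pipeline has two learned stages.

**Graph-convolutional autoencoder (GCAN) embedding.** Raw drug-induced
expression is noisy, and its correlation with chemical structure is weak.
The embedder strengthens that relationship by (1) building a drug-similarity
graph: pairwise Tanimoto similarity of fingerprints, keeping per row the 40
most similar other drugs, adding a unit self-weight, and normalizing each
row to sum to one; and (2) training an autoencoder whose every layer first
mixes each drug's features with its neighbours' (multiplication by the
row-stochastic graph), then applies a dense map and a nonlinearity. The
encoder is 977 → 640 → 512 with tanh activations; the decoder is
512 → 640 → 1024 with tanh on the hidden layer and a sigmoid output, trained
with mean per-bit binary cross-entropy against the fingerprint bits, Adam at
learning rate 1e-4, L2 penalty 1e-5 on the dense maps, and dropout 0.3 on
hidden layers. The 512-dimensional encoder output is the embedded feature.
Setting the graph to the identity yields the plain autoencoder baseline
(structure supervision without neighbour mixing). Embedding is transductive:
the graph over the full cohort is used, and cross-validation later splits
*pairs*, not drugs.

**Sequence classifier.** A pair (a, b) is stacked as a length-2 sequence of
feature vectors and fed to a two-layer LSTM (400 units per layer by
default), with the forget-gate bias initialised to 0.7 so cells start out
retentive; the final hidden state feeds a dense sigmoid head with one unit
per interaction type. Training uses per-type binary cross-entropy
(multi-label framing), Adam at 1e-4, dropout 0.5 on non-recurrent
connections, batch size 256 and L2 1e-5. Decoding predicts every type whose
score reaches 0.5 and falls back to the arg-max type when none does, so
each pair receives at least one label. The concatenation DNN baseline feeds
[f(a), f(b)] through dense ReLU layers into the same head; it sees order
only through the concatenation layout.

Where the architecture leaves choices open, the package fixes them as
follows: tanh on all hidden layers with sigmoid only at the decoder/head
output (the only combination under which a cross-entropy against binary
targets is well-defined); Adam as the optimizer; Glorot-uniform dense and
orthogonal recurrent initialisation, all seeded; full-batch training for
the embedder (cohorts of a few hundred drugs) and an optional
plateau-based early stop (patience 20, min-delta 1e-5 for the embedder;
patience 30 with a 10% validation split for the classifiers). "Forgetting
threshold 0.7" is read as the forget-gate bias initialisation value;
dropout is applied to hidden layers only. The networks are implemented
directly on NumPy arrays with hand-written backpropagation: at this scale
full-precision CPU training takes seconds to minutes, and explicit arrays
make every run bit-reproducible from one integer seed.

## Evaluation

Macro-recall and macro-precision average per-type recall TP/(TP+FN) and
precision TP/(TP+FP) over interaction types; macro-F1 is the harmonic mean
2PR/(P+R) of those two macro averages (not the mean of per-type F1 — the
two coincide only in symmetric cases). A type with a zero denominator
contributes 0, the conservative convention. Five-fold cross-validation
partitions pairs once, stratified by type (the gold-standard filter keeps
only types with at least 5 pairs precisely so each can appear in every
fold); summaries are reported as mean ± sample sd, rendered "xx.x% ± x.x%".
Method comparisons use a paired two-sided t-test over the per-fold values
(folds are paired by the shared partition); identical fold vectors report
p = 1.

Two diagnostics probe *why* embedding helps. The similarity-profile
correlation represents each drug by its vector of similarities to every
other drug — inverse-squared-distance similarity 1/(Σ(xᵢ−yᵢ)²+1) for
real-valued features, Tanimoto for fingerprints — and computes, per drug,
the Pearson correlation between its profile under the two feature spaces.
Self-similarity entries (identically 1 in both spaces) are excluded so a
shared constant cannot inflate the correlation; zero-variance rows are
reported missing and excluded from the median. The normalizer is the
standard deviation (the only normalization with r ∈ [−1, 1]). The
nearest-training-neighbour consistency reports the fraction of predicted
drugs whose single most similar training drug (ties broken by drug-id
order) lies in the concordant reference group.

## Synthetic data

The generator plants exactly the structure the method assumes, nothing
more. Drugs belong to a small number of latent structural classes; class
prototypes are Bernoulli(0.5) bit vectors and each drug's fingerprint is
its prototype with independent per-bit flips (`bit_flip_rate`, default
0.05). Signatures are a fixed seed-determined Gaussian linear map of the
fingerprint, scaled so per-gene signal is order one, plus i.i.d. Gaussian
noise (`expr_noise_sd`). The type of an ordered pair is a deterministic
function of the ordered class pair, and types left with fewer than
`pairs_per_type_min` (≥ 5) pairs are dropped, mirroring the gold-standard
preparation. Ordered pairs are sampled without replacement and (a, b) and
(b, a) are distinct records.

What this emulates — and what it does not: the generator reproduces the
*statistical skeleton* (structure-linked expression with tunable noise,
class-determined interaction types, the type-count floor) but not
cell-line effects, dose/time covariates, L1000 plate structure, or
realistic chemistry (fingerprints are sampled bits, not molecules; a small
list of real SMILES ships as fixtures for the RDKit path). Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted signal, not clinical performance on real DrugBank/LINCS data.

One property of i.i.d. gene noise deserves note: because profile
correlations average over 977 genes, independent noise largely cancels,
so only large noise levels (sd ≈ 20 at the default signal scale) push the
raw-signature structure correlation below 0.1. The correlation-recovery
study is run in that regime; the feature-comparison study uses moderate
noise (sd 10), where raw-feature classification is visibly degraded.

## Study conditions and numerical choices

The synthetic studies in `gcanddi.experiments` use desk-scale cohorts:
200 drugs / 8 classes for correlation recovery (3 seeds), 60 drugs / 240
pairs for noiseless label recovery, and 100 drugs / 400 pairs / 6 types
for the raw-versus-embedded comparison (5 seeds, held-out fold of a
seeded stratified 5-fold split of pairs). At these sizes the classifiers
use 64 LSTM units or (128, 64) dense layers and up to 600 epochs — widths
scaled to the cohort; all other hyperparameters keep their defaults. The
embedder trains 300 epochs in the studies (500 by default); on noiseless
fixtures it reaches per-bit reconstruction accuracy 1.0 within 1000
epochs at the stated learning rate.

Degenerate inputs are handled explicitly: Tanimoto of two all-zero
fingerprints is defined as 1 (identical objects, logged); a graph row with
no positive similarity falls back to its self-loop; ties at the k-th
neighbour rank break toward the lower drug index; an empty decoded label
set falls back to the arg-max type. Training aborts with an error naming
the epoch if the loss becomes non-finite.

## Known limitations

* Real-data acquisition (GCTx archives, DrugBank XML) is out of scope; the
  L1000 adapter consumes a documented text export only, and assumes the
  control subtraction is already reflected in the supplied values.
  Duplicate exemplar signatures for a compound are averaged.
* The classical baselines (Random Forest and k-NN multi-label variants)
  are reachable through a thin adapter that accepts any scikit-learn-style
  estimator; they are comparison points, not part of the model.
* With i.i.d. synthetic noise the plain autoencoder baseline can match or
  exceed the graph variant on the correlation diagnostic; the studies
  assert the embedding's gain over raw signatures, which is the claim the
  synthetic world can support.
* The LSTM advantage over the DNN on real interaction data is not asserted
  on synthetic data: planted types here are order-separable by both
  architectures.
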