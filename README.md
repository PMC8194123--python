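# gcanddi

Typed drug–drug interaction (DDI) prediction from drug-induced
transcriptome signatures, for computational pharmacology and
drug-safety researchers.

Combination pharmacotherapy makes adverse DDIs a leading source of
preventable harm, and most computational DDI predictors rely on chemical
structure alone. This package implements a transcriptome-first pipeline:

1. **GCAN embedding** — a graph-convolutional autoencoder embeds each
   drug's 977-dimensional landmark-gene differential-expression signature
   into 512 dimensions. Every layer mixes a drug's features with those of
   its 40 most structurally similar neighbours (row-normalized Tanimoto
   similarity of 1024-bit Morgan fingerprints), and the decoder is trained
   to reconstruct the drug's own fingerprint with per-bit cross-entropy —
   so the embedding keeps the structure-related component of noisy
   expression data. Encoder 977→640→512 (tanh), decoder 512→640→1024
   (sigmoid output), Adam 1e-4, L2 1e-5, dropout 0.3.
2. **Sequence LSTM classifier** — an ordered pair (a, b) is a length-2
   sequence of embedded vectors into a two-layer, 400-unit LSTM
   (forget-gate bias 0.7) with a per-type sigmoid head; types scoring
   ≥ 0.5 are predicted, with arg-max fallback. A concatenation DNN and an
   adapter for classical multi-label baselines provide comparisons.

Evaluation follows the field's macro-averaged convention: macro-recall
R = mean_i TP_i/(TP_i+FN_i), macro-precision P = mean_i TP_i/(TP_i+FP_i),
macro-F1 = 2PR/(P+R), under stratified five-fold cross-validation of pairs
with paired t-tests across folds. Similarity-profile diagnostics
(per-drug Pearson correlation between a drug's similarity profile under
expression features, s(x,y) = 1/(‖x−y‖²+1), and under Tanimoto structure
similarity) quantify how much the embedding re-aligns expression with
structure.

A seeded synthetic-data generator plants the structure the method assumes
(latent structural classes, fingerprints as noisy class prototypes,
signatures as a noisy linear map of structure, interaction types as a
function of class pairs, the ≥ 5-pairs-per-type floor), so the entire
pipeline is testable without any external download. Interfaces to real
data are delimited-text only (a drug table with SMILES and signature
columns, a typed pair list, and a documented L1000-style text export
adapter).

## Worked example

```python
from gcanddi import (SimulationConfig, simulate_drugs, simulate_ddis,
                     build_similarity_graph, GCANEmbedder,
                     LSTMDdiClassifier, pair_design_matrix, fivefold_cv)
from gcanddi.gcan import EmbeddedFeatures

config = SimulationConfig(n_drugs=60, n_classes=3, n_types=4,
                          expr_noise_sd=1.0, seed=11)
drugs = simulate_drugs(config)
ddis = simulate_ddis(drugs, config)

graph = build_similarity_graph(drugs.fingerprints, drug_ids=drugs.ids, k=40)
gcan = GCANEmbedder(epochs=300, random_state=11)
gcan.fit(drugs.signatures, drugs.fingerprints, graph=graph)
features = EmbeddedFeatures(drugs.ids, gcan.embedding_, kind="gcan")

X = pair_design_matrix(features, ddis.pairs)
y = ddis.pairs["type_label"].to_numpy()
folds, summary = fivefold_cv(LSTMDdiClassifier(units=64, epochs=400,
                                               random_state=11), X, y, seed=11)
print(summary["macro_f1"]["formatted"])
```

This prints `93.1% ± 4.4%` — the five-fold macro-F1 (mean ± sample sd)
of the sequence LSTM on embedded features for a 60-drug cohort with mild
expression noise, where the planted class-determined interaction types
are nearly fully recoverable. Raising `expr_noise_sd` degrades
raw-signature performance long before embedded-feature performance, and
the noiseless regime is an exact correctness oracle (training macro-F1
reaches 1.0); see the studies in `gcanddi.experiments`.

The same pipeline is scriptable from the shell:

```bash
gcanddi simulate --config sim.yaml --out-dir data/
gcanddi build-graph --drugs data/drugs.tsv --fingerprints data/fingerprints.tsv \
    --k 40 --out data/graph.tsv
gcanddi train-gcan --drugs data/drugs.tsv --fingerprints data/fingerprints.tsv \
    --graph data/graph.tsv --out runs/gcan/
gcanddi train-ddi --pairs data/ddis.tsv --features runs/gcan/embeddings.tsv \
    --model lstm --out runs/lstm/
```

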