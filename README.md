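# gcgrader

Grading granulosa-cell fertility potential from single-cell transcriptomes.

Granulosa cells (GCs) surround the developing oocyte and their expression
profiles track its developmental competence, so the fraction of
*fertility-supporting* (FS) GCs in an ovarian sample is a candidate
molecular fertility score — for example, to compare a monotocous
(single-offspring) and a polytocous (multi-offspring) animal. `gcgrader`
implements an end-to-end procedure that turns two cell × gene count
matrices into that score:

1. **QC and normalization.** Cells are retained when they have ≥ 10,000
   total counts, ≥ 1,500 detected genes, and < 25% mitochondrial reads;
   retained cells are scaled to counts-per-million (CPM).
2. **Model-training DEGs.** A Welch t-test on log1p CPM with
   Benjamini–Hochberg FDR control selects genes with q ≤ 0.01 and
   |log2FC| ≥ 1.5 between the two samples. These genes are the
   classifier's feature signature.
3. **Cluster-purity pseudo-labels.** Cells from both samples are pooled,
   their DEG-restricted profiles are min–max scaled, and Leiden community
   detection (k = 15 kNN graph, resolution 0.5) partitions them. Clusters
   with ≥ 75 cells whose composition is ≥ 80% polytocous are labeled FS;
   ≥ 80% monotocous clusters are labeled NFS; everything else stays
   unlabeled.
4. **Hybrid 1D-CNN/GRU classifier.** The pseudo-labeled profiles train a
   sequence model — Conv1D(64 filters, kernel 2, ReLU) → BatchNorm →
   MaxPool(2) → Dropout → GRU(64) → LayerNorm → Dense(192, ReLU) →
   Dropout → Dense(2, sigmoid) — with categorical cross-entropy and Adam
   (lr 10⁻³, 10 epochs, batch 32, stratified 80/20 test split, 30%
   validation split, early stopping). The GRU follows the standard gate
   recursion
   `z_t = σ(U_z x_t + W_z h_{t−1} + b_z)`,
   `r_t = σ(U_r x_t + W_r h_{t−1} + b_r)`,
   `h̃_t = tanh(W_h (r_t ⊙ h_{t−1}) + U_h x_t + b_h)`,
   `h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t`.
5. **Confidence-thresholded quantification.** Each cell is assigned its
   arg-max class only when the normalized class probability reaches 0.95;
   otherwise it is *ambiguous* and excluded. The FS percentage is
   100 · FS / (FS + NFS) over confident cells. Within-sample DEG analysis
   between predicted classes, a three-set Venn decomposition against the
   model-training DEGs, and upper-tail hypergeometric overlap tests
   validate that the classifier generalizes.

The classifier is implemented in a self-contained, fully deterministic
numpy engine (vectorized forward/backward passes with Adam), accompanied
by an independent scalar-loop reference forward pass used to verify the
layer equations term by term.

A first-class synthetic-data generator (`gcgrader.simulate`) emulates the
two-sample study design — negative-binomial counts, per-cell depth
variation, planted FS/NFS mixtures at chosen proportions, and a planted
DEG signature at a chosen log2 fold change — so every stage is testable
against known ground truth without any download.

## Worked example

```python
import gcgrader as g

sim = g.SimulationConfig(
    n_cells_per_sample=(1000, 1000), n_genes=200, n_deg=40,
    planted_log2fc=2.0, fs_fraction=(0.10, 0.85), seed=1,
)
model = g.GranulosaFertilityModel.from_simulation(sim)
results = model.fit()
print(results.summary())
```

prints

```
Granulosa-cell fertility grading results
========================================================
Model-training DEGs (features): 9
Leiden clusters: 4  (FS clusters: [1, 2, 3], NFS clusters: [0])
Pseudo-labeled training cells: 969 FS / 1031 NFS
--------------------------------------------------------
Held-out test metrics (FS = positive class):
  accuracy  100.00%    precision 100.00%
  recall    100.00%    F1        100.00%
  confusion TP=194 FN=0 TN=206 FP=0
--------------------------------------------------------
Confidence threshold: 0.95
  monotocous    1000 cells: 115 FS, 884 NFS, 1 ambiguous -> FS 11.51% of confident (11.50% of all)
  polytocous    1000 cells: 851 FS, 147 NFS, 2 ambiguous -> FS 85.27% of confident (85.10% of all)
--------------------------------------------------------
DEG-set sizes: model_training=9, polytocous=40, monotocous=40
Common to all three sets: 9 genes (universe 200)
  overlap model_training|polytocous: 9 genes, hypergeometric p = 2.33e-07
  overlap model_training|monotocous: 9 genes, hypergeometric p = 2.33e-07
--------------------------------------------------------
Ground truth: pseudo-label concordance 99.05%, planted-DEG recovery polytocous 100.0%, monotocous 100.0%
```

Reading the output: of the 40 planted DEGs, 9 survive the cross-sample
fold-change gate once the two samples are mixtures (an 85%/10% FS mixture
dilutes a 4-fold single-cell effect to about 2.7-fold at the sample
level), and those 9 genes are the trained signature. The estimated FS
shares — 85.3% of confident polytocous cells, 11.5% of confident
monotocous cells — recover the planted 85%/10% composition, and the
within-sample DEG sets between *predicted* classes recover all 40 planted
genes, because the predicted classes are nearly pure. Both within-sample
DEG sets overlap the training signature far beyond chance (hypergeometric
p ≈ 2 × 10⁻⁷ against the 200-gene universe).

The same run is available from a shell:

```sh
gcgrader run-all --synthetic --outdir run1 --seed 1
```

which writes the count matrices, every stage table, the fitted model
bundle, and `manifest.json` with per-stage seeds and artifact checksums.

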