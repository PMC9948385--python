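# doublecluster

Joint, unsupervised discovery of **cell-type vocabularies** and **patient
phenotype clusters** from cytometry-style data, in one probabilistic workflow.

Cell-level assays (flow cytometry, and count data such as microbial genus
abundances) produce one matrix per patient — thousands of cells by a handful
of fluorescence markers — with no correspondence between the cells of
different patients. Stratifying patients from such data therefore requires
two couplings at once: grouping cells into shared populations, and grouping
patients by how their cells distribute over those populations. This package
solves the two together:

1. **Cell typing.** All patients' cells are pooled, standardized with a
   single Z-score, and partitioned by K-means into `W = 2^N` clusters
   (`N` = number of markers). Each cluster is a "word".
2. **Counting.** Every cell of every patient is assigned to its nearest
   centroid, giving a patients × cell-types count matrix — each patient is a
   "document" of cell-type tokens.
3. **Topic modelling.** A latent Dirichlet allocation with `K` topics is fit
   to the counts by collapsed Gibbs sampling, with priors
   `θ_d ~ Dirichlet(α)` (patient → topic mixture) and `φ_k ~ Dirichlet(β)`
   (topic → cell-type distribution). The token conditional is

   ```
   P(z_i = j | z_-i, w_i, d_i) ∝  (C^WK[w,j] + β) / (Σ_w C^WK[w,j] + Wβ)
                                · (C^DK[d,j] + α) / (Σ_k C^DK[d,k] + Kα)
   ```

   with `C^WK`, `C^DK` the word–topic and document–topic count matrices
   excluding token `i`. Patients are assigned to `argmax_k θ[d,k]`, and the
   Bayes-inverted `P(topic | cell type)` identifies the cell populations that
   drive each phenotype.

Pre-made nonnegative count tables (e.g. 16S genus abundances) enter at step 3
directly. The package also ships a synthetic cohort simulator with known
ground truth, label-switching-aware evaluation (majority vote, balanced
repeated subsampling, a K-means-on-counts baseline), and consensus
co-assignment networks built from repeated runs.

## Worked example

`examples/02_double_cluster.py` simulates a two-class cohort (40 patients,
1000 cells each, 2 markers, class vectors at Euclidean distance 0.5, marker
noise σ = 0.25) and runs the full workflow:

```
patients: 40, vocabulary W=4, K=2 topics
majority-vote accuracy vs ground truth: 1.000
cluster -> class mapping: {0: 0, 1: 1}

theta rows (first 3 patients), P(topic | patient):
[[0.851 0.149]
 [0.866 0.134]
 [0.867 0.133]]

phi, P(cell type | topic):
[[0.017 0.48  0.417 0.086]
 [0.479 0.02  0.419 0.082]]

P(topic | cell type) — which topic 'owns' each cell type:
[[0.035 0.965]
 [0.96  0.04 ]
 [0.498 0.502]
 [0.512 0.488]]
```

Every patient lands in its true class (accuracy 1.0 after the majority-vote
mapping that resolves label switching). The `P(topic | cell type)` rows show
two cell populations almost exclusively associated with one phenotype each
(0.97/0.96) and two shared ones — the per-cell-type view that makes the
clustering interpretable. The other examples cover the simulator
(`01`), direct count-table input (`03`), balanced evaluation of unbalanced
cohorts (`04`), and consensus networks (`05`).

A thin CLI wraps the same functions:

```bash
doublecluster simulate --config cohort.json --out cohort/
doublecluster fit cohort/manifest.tsv -k 2 --out fit/
doublecluster evaluate --assignments fit/assignments.tsv --truth truth.tsv --out report.json
doublecluster consensus cohort/manifest.tsv -k 2 --n-runs 40 --out net/
```

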