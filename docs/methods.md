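# Methods

## Model

Patients are treated as documents over a discrete vocabulary of cell types.
Given a patients × cell-types count matrix `n` (D documents, W words), the
model is standard latent Dirichlet allocation: each patient `d` has a topic
mixture `θ_d ~ Dirichlet(α·1_K)`, each topic `k` a word distribution
`φ_k ~ Dirichlet(β·1_W)`, and each cell-type token draws a topic
`z ~ θ_d` then a word `w ~ φ_z`. Topics play the role of patient
phenotypes; words are the cell populations (or, for abundance tables,
bacterial genera). `θ` and `φ` are integrated out and inference runs on the
token–topic assignments by collapsed Gibbs sampling; the token conditional
is the usual product of smoothed word–topic and document–topic ratios, with
the current token removed from the counts.

Assumptions worth stating: tokens are exchangeable within a patient (cell
order carries no information); the number of topics `K` is fixed by the user
(2 for a case/control split; more for exploratory stratification); and the
vocabulary is fixed before the topic model runs — zero counts are legitimate,
never pruned, so `W` stays at `2^N`.

### Estimation

* Initialization: `z_i ~ Uniform{0..K−1}` i.i.d. from the sampler seed.
* Scan order: deterministic, document-major, token order within document —
  a valid systematic Gibbs scan, fully reproducible.
* Chain schedule: 500 sweeps, 200 burn-in, every 10th sweep retained.
  `θ` and `φ` are the smoothed-count estimates
  `θ[d,k] = (C^DK[d,k]+α)/(n_d+Kα)`, `φ[k,w] = (C^WK[w,k]+β)/(n_k+Wβ)`
  averaged over retained samples of a single chain. No within-chain topic
  relabelling is applied; averaging within one converged chain is standard
  at this corpus scale (D ≈ 100 short documents), and alignment against
  external labels happens downstream via majority vote.
* The collapsed joint log-likelihood (Dirichlet-multinomial normalizers in
  log-gamma form) is recorded every sweep for convergence monitoring; no
  automatic stopping rule is applied.
* The inner sweep is numba-jitted; all randomness comes from one numpy
  `Generator` (one uniform per token per sweep), so results are bitwise
  reproducible for a given seed and the kernel stays pure bookkeeping.

Defaults: `α = 1.0` (mild document–topic smoothing, appropriate for ~100
documents), `β = 0.1` (small, encouraging crisp cell-type/topic
association). Both are exposed in the configuration; none of the reported
behaviour is sensitive to mild changes of either.

### Reported conditionals

Besides `θ` and `φ`, the workflow reports the Bayes-inverted
`P(topic k | cell type w) ∝ φ[k,w] · m_k`, with `m_k` the empirical topic
mass `Σ_d θ[d,k]·n_d / Σ_d n_d` — the per-cell-type view used to read off
which populations drive which phenotype. For individual cells the token
posterior `P(z = k | w, d) ∝ φ[k,w]·θ[d,k]` is available; a confidence
threshold (0.9 by default in reporting) selects high-confidence cells for
visualization with any external embedder.

## Cell typing

Standardization is pooled-global: the Z-score mean and standard deviation
come from the concatenation of **all** patients' cells and are reused for any
later assignment, keeping the vocabulary transferable. K-means uses
k-means++ initialization, 10 restarts, a 300-iteration cap, tolerance 1e-4,
and a fixed seed; nearest-centroid ties break to the lowest cluster index.
Degenerate inputs fail fast: a zero-variance marker, or `W` larger than the
number of distinct pooled points, raises with a descriptive message.

## Synthetic cohorts

The simulator emulates the structure of pre-processed cytometry data:

* Each of `N` markers is a two-component Gaussian mixture with means
  `mu_low = 0`, `mu_high = 1` and a shared standard deviation `sigma`
  (default 0.25) — the explicit robustness knob; larger `sigma` makes low
  and high states harder to separate. A cell's discrete phenotype is its
  N-bit high/low code (bit `j` of type `t` is `(t >> j) & 1`), giving
  `W = 2^N` possible cell types.
* Each patient class has a probability vector over the `W` cell types,
  constructed as `clip(u + (distance/√2)·h_c, 0)` renormalized, where `u` is
  uniform and the `h_c` are orthonormal zero-sum signatures (scaled Hadamard
  rows for power-of-two `W`, Helmert rows otherwise; the seed permutes which
  cell types each signature enriches). Orthogonality makes every pairwise
  Euclidean distance equal to `distance` exactly when no clipping occurs.
  This gives the difficulty axis a single interpretable knob. Geometry caps
  the admissible separation: entries clip at zero once
  `distance > √2·min(u)/|h|`, i.e. at ≈ 0.707 for two classes at `W = 4`
  and ≈ 0.354 for four classes at `W = 16`; if clipping distorts any
  achieved pairwise distance by more than 10% of the target the constructor
  refuses rather than silently delivering a different geometry.
* Cohorts default to 50 patients per phenotype and 10⁴ cells per patient
  (tests and the acceptance protocol scale down to 20 patients and 10³
  cells to keep runtimes in seconds; all qualitative behaviour is identical
  at full scale, with even tighter multinomial noise). Each patient draws an
  independent substream spawned from the root seed, so a patient's cells do
  not depend on cohort size, and the whole cohort is a pure function of its
  spec.

Not emulated: doublets, spillover/compensation, batch effects, non-Gaussian
marker noise, or any real marker panel. Passing tests on this generator
demonstrate the correctness and stability of the workflow, not performance
on real instruments' artefacts.

### What the difficulty knob actually does

A note on separability, since it determines what the simulated regimes can
show. At the default noise (`sigma = 0.25` against a unit mean gap), the
per-marker low/high misassignment rate is ≈ 2.3%, so the learned vocabulary
is essentially the true cell types, and a patient's count vector estimates
its class vector with multinomial noise only (sd ≈ 0.014 per component at
10³ cells). Even at `distance = 0.1` the classes are then several noise
standard deviations apart, and the workflow — or the plain K-means baseline —
recovers them almost perfectly, as the acceptance script shows. Chance-level
accuracy at small distances arises only when the marker mixtures overlap
strongly (`sigma` of order the mean gap or larger), where cell-type
assignment destroys most of the class signal before the topic model ever
sees it. `sigma` is the parameter to raise to study that regime.

## Evaluation

* **Majority vote**: each predicted cluster maps to the most frequent true
  label among its members (ties to the earliest label in sorted order; two
  clusters may map to one label), and accuracy is scored under that mapping.
  This resolves label switching and, for balanced two-class truth, bounds
  accuracy below by 0.5 — the relevant chance level.
* **Balanced repeated subsampling** (20 repetitions by default): each
  repetition uniformly samples, without replacement and afresh, the
  minority-class number of patients from every class, refits the topic model
  on the subsample, and scores it. This is deliberately *not* partition-based
  cross-validation: clustering has no train/test split, and accuracy is
  computed on the sampled set itself. The per-repetition accuracies are
  exposed so any external test can be run on them.
* **Baseline**: K-means (same settings as cell typing) on count rows
  normalized to per-patient frequencies (absolute cell totals are a nuisance
  scale; a flag disables the normalization).

## Consensus networks

The workflow is rerun `n_runs` times (default 40) with consecutive seeds —
both the sampler seed and, for the cell-matrix path, the K-means seed vary,
so the ensemble is reproducible as a unit from one base seed (a flag freezes
cell typing, which also matches the count-table path where none exists). The
co-assignment matrix records the fraction of runs in which each patient pair
shares a cluster; the diagonal is fixed at 1 by convention and self-edges are
excluded. Pairs at or above the threshold (default 0.30; pairs co-clustered
in strictly fewer runs are removed) become edges, node degree is recorded for
display scaling, and the graph exports to GraphML and a plain edge-list TSV.
Raising the threshold can only remove edges.

## Known limitations

* Single-chain inference; no between-chain convergence diagnostics beyond
  the log-likelihood trace.
* No automatic selection of `K` (a grid over `K` is trivial to script; no
  selection criterion is built in) and no hierarchical topic structure.
* FCS files are not read directly; cytometry input is CSV/TSV per patient
  (real FCS preprocessing — gating, compensation, transforms — is upstream
  of this tool).
* The equidistant-class construction bounds the reachable separation per
  (number of classes, W) geometry, as quantified above; beyond it the
  constructor raises rather than approximates.
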