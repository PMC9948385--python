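"""Run the full double-clustering workflow on a simulated cohort.

Cell typing (pooled Z-score + K-means into W=4 cell types), then the
collapsed-Gibbs topic model with K=2 topics over the per-patient counts, and
finally majority-vote accuracy against the simulator's ground truth.
"""

import numpy as np

from doublecluster import (
    CohortSpec,
    double_cluster,
    majority_vote_accuracy,
    simulate_cohort,
)

spec = CohortSpec(
    n_markers=2, n_phenotypes=2, patients_per_phenotype=20,
    cells_per_patient=1000, sigma=0.25, distance=0.5, seed=7,
)
cohort, labels, _ = simulate_cohort(spec)
result = double_cluster(cohort, k_topics=2, lda_seed=7, celltyping_seed=7)

report = majority_vote_accuracy(result.patient_assignments, labels)
print(f"patients: {len(cohort)}, vocabulary W={result.counts.W}, K=2 topics")
print(f"majority-vote accuracy vs ground truth: {report.accuracy:.3f}")
print(f"cluster -> class mapping: {report.cluster_to_label}")

print("\ntheta rows (first 3 patients), P(topic | patient):")
print(np.round(result.theta[:3], 3))
print("\nphi, P(cell type | topic):")
print(np.round(result.phi, 3))
print("\nP(topic | cell type) — which topic 'owns' each cell type:")
print(np.round(result.celltype_topic, 3))
print("-> rows near (1,0) or (0,1) mark cell types tied to one phenotype.")
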