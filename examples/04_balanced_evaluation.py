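"""Evaluate clustering on an unbalanced cohort with repeated balanced sampling.

An unbalanced two-class count corpus (8 vs 24 patients) is scored with 20
repetitions of balanced subsampling: each repetition draws 8 patients per
class uniformly, reruns the topic model on the subsample, and scores
majority-vote accuracy.  The K-means-on-frequencies baseline is run on the
full cohort for comparison.
"""

import numpy as np

from doublecluster import (
    CountMatrix,
    balanced_cv,
    kmeans_patient_baseline,
    majority_vote_accuracy,
)

rng = np.random.default_rng(3)
rows = np.vstack(
    [rng.multinomial(500, [0.45, 0.3, 0.15, 0.1]) for _ in range(8)]
    + [rng.multinomial(500, [0.1, 0.15, 0.3, 0.45]) for _ in range(24)]
)
labels = np.array([0] * 8 + [1] * 24)
counts = CountMatrix(rows, [f"P{i:02d}" for i in range(32)], W=4)

report = balanced_cv(counts, labels, k_topics=2, n_folds=20, seed=0)
folds = np.array(report.per_fold_accuracies)
print(f"balanced resampling (20 reps of 8+8 patients):")
print(f"  mean accuracy {report.accuracy:.3f}  (per-fold sd {folds.std():.3f})")

baseline = kmeans_patient_baseline(counts, K=2, seed=0)
acc = majority_vote_accuracy(baseline, labels).accuracy
print(f"K-means-on-frequencies baseline, full cohort: accuracy {acc:.3f}")
print("-> on separable corpora both routes score near 1.0; the topic model")
print("   additionally yields P(feature | cluster) for interpretation.")
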