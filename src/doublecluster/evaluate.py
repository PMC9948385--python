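"""Clustering evaluation: majority-vote accuracy, balanced resampling, baseline.

Cluster indices are arbitrary (label switching), so accuracy is scored after
mapping each predicted cluster to the most frequent true label among its
members.  Class imbalance is handled by repeated balanced subsampling: each
repetition draws the same number of patients per class uniformly without
replacement, reruns the topic-model clustering on the subsample, and scores it.
A K-means-on-count-frequencies baseline is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .celltyping import KMEANS_KWARGS, CountMatrix
from .lda import LDAHyperparams, fit_lda

__all__ = [
    "EvaluationReport",
    "majority_vote_accuracy",
    "balanced_cv",
    "kmeans_patient_baseline",
]


@dataclass
class EvaluationReport:
    accuracy: float
    cluster_to_label: dict = field(default_factory=dict)
    per_fold_accuracies: list[float] | None = None
    n_folds: int | None = None


def majority_vote_accuracy(pred, truth) -> EvaluationReport:
    """Accuracy after mapping each predicted cluster to its majority true label.

    Ties go to the label earliest in sorted order.  Two clusters may map to the
    same label; for balanced two-class truth this bounds accuracy at >= 0.5.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty prediction vector")

    labels = sorted(set(truth.tolist()))
    mapping = {}
    for c in np.unique(pred):
        members = truth[pred == c]
        counts = {lab: int(np.sum(members == lab)) for lab in labels}
        best = max(counts.values())
        mapping[int(c)] = next(lab for lab in labels if counts[lab] == best)
    mapped = np.array([mapping[int(c)] for c in pred])
    return EvaluationReport(
        accuracy=float(np.mean(mapped == truth)), cluster_to_label=mapping
    )


def balanced_cv(
    counts: CountMatrix,
    labels,
    k_topics: int,
    n_folds: int = 20,
    seed: int = 0,
    hp: LDAHyperparams | None = None,
) -> EvaluationReport:
    """Repeated balanced subsampling of the cohort, reclustered per repetition.

    Each of the ``n_folds`` repetitions uniformly samples (without replacement,
    fresh per repetition) the minority-class number of patients from every
    class, fits the topic model on the subsample, and scores majority-vote
    accuracy on it.  Reports the mean and the per-repetition accuracies.
    """
    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if class_counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    n_per_class = int(class_counts.min())

    rng = np.random.default_rng(seed)
    if hp is None:
        hp = LDAHyperparams(K=k_topics)
    fold_accs: list[float] = []
    for _ in range(n_folds):
        idx = np.concatenate(
            [
                rng.choice(np.flatnonzero(labels == c), n_per_class, replace=False)
                for c in classes
            ]
        )
        sub = counts.subset(idx)
        fold_hp = replace(hp, seed=int(rng.integers(0, 2**31 - 1)))
        model, _ = fit_lda(sub, fold_hp)
        fold_accs.append(
            majority_vote_accuracy(model.assignments, labels[idx]).accuracy
        )
    return EvaluationReport(
        accuracy=float(np.mean(fold_accs)),
        per_fold_accuracies=fold_accs,
        n_folds=n_folds,
    )


def kmeans_patient_baseline(
    counts: CountMatrix, K: int, seed: int = 0, normalize: bool = True
) -> np.ndarray:
    """Cluster patients directly with K-means on their count rows.

    Rows are normalized to per-patient cell-type frequencies by default, since
    absolute cell totals are a nuisance scale.  Same K-means settings as cell
    typing; compare against the topic-model path with
    :func:`majority_vote_accuracy`.
    """
    if counts.n_patients < K:
        raise ValueError(f"D={counts.n_patients} < K={K}")
    x = counts.counts.astype(float)
    if normalize:
        totals = x.sum(axis=1, keepdims=True)
        x = np.divide(x, totals, out=np.zeros_like(x), where=totals > 0)
    km = KMeans(n_clusters=K, random_state=seed, **KMEANS_KWARGS).fit(x)
    return km.labels_
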