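"""End-to-end double-clustering workflow.

From per-patient cell matrices: pool, standardize, K-means into ``W`` cell
types, count cells per type per patient, then fit the collapsed-Gibbs topic
model with ``K`` topics; each patient is assigned to the topic maximizing its
theta row.  A pre-made count matrix (e.g. a genus abundance table) enters the
same workflow directly, skipping cell typing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .celltyping import CellTypeModel, CountMatrix, assign_and_count, fit_cell_types
from .lda import LDAHyperparams, TopicModel, fit_lda
from .simulate import PatientCellMatrix

__all__ = [
    "DoubleClusteringResult",
    "double_cluster",
    "celltype_topic_distribution",
    "cell_topic_posterior",
]


@dataclass
class DoubleClusteringResult:
    """Everything the workflow estimates.

    ``celltype_topic`` is the Bayes-inverted P(topic | cell type) (rows sum
    to 1), the per-cell-type view of the fit; ``phi`` holds the direct
    P(cell type | topic).  ``cell_model`` is ``None`` when the input was a
    pre-made count matrix.
    """

    patient_assignments: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    celltype_topic: np.ndarray
    counts: CountMatrix
    topic_model: TopicModel
    cell_model: CellTypeModel | None
    config_echo: dict


def celltype_topic_distribution(
    phi: np.ndarray, theta: np.ndarray, counts: CountMatrix
) -> np.ndarray:
    """Invert phi to P(topic k | cell type w), one row per cell type.

    P(k | w) ∝ phi[k, w] * m_k with the empirical topic mass
    m_k = sum_d theta[d, k] * len(d) / sum_d len(d).
    """
    lengths = counts.row_sums.astype(float)
    total = lengths.sum()
    if total == 0:
        raise ValueError("zero total mass: empty corpus")
    mass = theta.T @ lengths / total  # (K,)
    joint = phi * mass[:, None]  # (K, W)
    col = joint.sum(axis=0)
    return (joint / col).T  # (W, K)


def cell_topic_posterior(
    d: int, w: int, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Posterior topic distribution of one cell: P(z=k | w, d) ∝ phi[k,w]*theta[d,k].

    Thresholding the maximum of this vector (0.9 by default in reporting)
    selects the high-confidence cells used for per-cell visualization.
    """
    p = phi[:, w] * theta[d]
    return p / p.sum()


def double_cluster(
    data: list[PatientCellMatrix] | CountMatrix,
    k_topics: int,
    *,
    hp: LDAHyperparams | None = None,
    w: int | None = None,
    celltyping_seed: int = 0,
    lda_seed: int = 0,
) -> DoubleClusteringResult:
    """Run the full workflow on a cohort of cell matrices or a count table.

    Parameters
    ----------
    data
        Either a list of :class:`PatientCellMatrix` (cell-typing path) or a
        ready :class:`CountMatrix` (direct path, no cell typing).
    k_topics
        Number of patient clusters (topics); fixed by the user.
    hp
        Full sampler configuration; defaults to ``LDAHyperparams(K=k_topics,
        seed=lda_seed)``.
    w
        Vocabulary size for cell typing; defaults to ``2**n_markers``.
    """
    if k_topics < 1:
        raise ValueError("k_topics must be >= 1")
    if hp is None:
        hp = LDAHyperparams(K=k_topics, seed=lda_seed)
    elif hp.K != k_topics:
        raise ValueError(f"hp.K={hp.K} disagrees with k_topics={k_topics}")

    cell_model: CellTypeModel | None = None
    if isinstance(data, CountMatrix):
        counts = data
    else:
        if w is None:
            w = 2 ** data[0].n_markers
        cell_model = fit_cell_types(data, W=w, seed=celltyping_seed)
        counts = assign_and_count(data, cell_model)

    if k_topics > counts.n_patients:
        raise ValueError(
            f"more clusters than patients: K={k_topics} > D={counts.n_patients}"
        )

    topic_model, _ = fit_lda(counts, hp)
    ct = celltype_topic_distribution(topic_model.phi, topic_model.theta, counts)
    return DoubleClusteringResult(
        patient_assignments=topic_model.assignments,
        theta=topic_model.theta,
        phi=topic_model.phi,
        celltype_topic=ct,
        counts=counts,
        topic_model=topic_model,
        cell_model=cell_model,
        config_echo={
            "k_topics": k_topics,
            "w": counts.W,
            "celltyping_seed": celltyping_seed,
            "alpha": hp.alpha,
            "beta": hp.beta,
            "n_iterations": hp.n_iterations,
            "n_burnin": hp.n_burnin,
            "thin": hp.thin,
            "lda_seed": hp.seed,
        },
    )
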