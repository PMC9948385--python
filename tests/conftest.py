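"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from doublecluster import CohortSpec, CountMatrix, simulate_cohort


def make_counts(rows, ids=None) -> CountMatrix:
    rows = np.asarray(rows, dtype=np.int64)
    ids = ids or [f"P{i}" for i in range(rows.shape[0])]
    return CountMatrix(counts=rows, patient_ids=ids, W=rows.shape[1])


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return make_counts([[2, 0, 1], [0, 3, 0], [1, 1, 1]])


@pytest.fixture
def separable_cohort():
    """Well-separated 2-class cohort, small enough for fast unit tests."""
    spec = CohortSpec(
        n_markers=2,
        n_phenotypes=2,
        patients_per_phenotype=10,
        cells_per_patient=500,
        sigma=0.1,
        distance=0.7,
        seed=11,
    )
    cohort, labels, vectors = simulate_cohort(spec)
    return spec, cohort, labels, vectors


def chain_rule_joint_logp(words, docs, z, W, K, alpha, beta) -> float:
    """Independent oracle for the collapsed joint log P(w, z | alpha, beta).

    Sequential product of predictive probabilities: token i picks its topic
    with probability (n_dk + alpha)/(n_d + K*alpha) and emits its word with
    probability (n_wk + beta)/(n_k + W*beta), all counts restricted to tokens
    before i.  Structurally different from the log-gamma closed form.
    """
    n_wk = np.zeros((W, K))
    n_dk = {}
    n_k = np.zeros(K)
    logp = 0.0
    for w, d, k in zip(words, docs, z):
        dk = n_dk.setdefault(d, np.zeros(K))
        logp += np.log((dk[k] + alpha) / (dk.sum() + K * alpha))
        logp += np.log((n_wk[w, k] + beta) / (n_k[k] + W * beta))
        dk[k] += 1
        n_wk[w, k] += 1
        n_k[k] += 1
    return logp


def enumerate_coassignment(words, docs, W, K, alpha, beta) -> np.ndarray:
    """Exact posterior pairwise co-assignment P(z_i == z_j | w) by enumeration."""
    T = len(words)
    coassign = np.zeros((T, T))
    logps = []
    zs = list(itertools.product(range(K), repeat=T))
    for zvec in zs:
        logps.append(chain_rule_joint_logp(words, docs, zvec, W, K, alpha, beta))
    logps = np.array(logps)
    weights = np.exp(logps - logps.max())
    weights /= weights.sum()
    for zvec, wgt in zip(zs, weights):
        za = np.array(zvec)
        coassign += wgt * (za[:, None] == za[None, :])
    return coassign
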