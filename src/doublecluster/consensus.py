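"""Patient co-assignment consensus networks from repeated clustering runs.

The workflow is stochastic (K-means and Gibbs seeds), so stability is probed
by rerunning it many times (40 by default) and counting, for every pair of
patients, the fraction of runs in which they land in the same cluster.
Thresholding that frequency matrix (keep pairs clustered together in at least
30% of runs, by default) gives a patient graph whose connected components and
node degrees summarize the reproducible structure of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .celltyping import CountMatrix
from .lda import LDAHyperparams
from .pipeline import double_cluster
from .simulate import PatientCellMatrix

__all__ = [
    "ConsensusNetwork",
    "coassignment_matrix",
    "build_network",
    "run_consensus",
    "write_graphml",
    "write_edge_list",
    "write_freq_matrix",
]


@dataclass
class ConsensusNetwork:
    """Thresholded co-assignment graph over the cohort.

    ``freq`` is symmetric with unit diagonal (self-similarity by convention);
    ``edges`` holds ``(i, j, weight)`` with ``i < j`` and ``weight >= threshold``
    (pairs co-clustered in strictly fewer runs are removed); ``degrees`` counts
    kept edges per patient.
    """

    freq: np.ndarray
    threshold: float
    edges: list[tuple[int, int, float]]
    degrees: np.ndarray
    patient_ids: list[str] = field(default_factory=list)
    node_attrs: dict[str, list] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        n = self.freq.shape[0]
        ids = self.patient_ids or [str(i) for i in range(n)]
        for i in range(n):
            attrs = {k: v[i] for k, v in self.node_attrs.items()}
            g.add_node(ids[i], degree=int(self.degrees[i]), **attrs)
        for i, j, wgt in self.edges:
            g.add_edge(ids[i], ids[j], weight=float(wgt))
        return g

    def connected_components(self) -> list[set[int]]:
        g = nx.Graph()
        g.add_nodes_from(range(self.freq.shape[0]))
        g.add_edges_from((i, j) for i, j, _ in self.edges)
        return [set(c) for c in nx.connected_components(g)]


def coassignment_matrix(runs: list[np.ndarray]) -> np.ndarray:
    """Fraction of runs in which each pair of patients shares a cluster."""
    if not runs:
        raise ValueError("need at least one run")
    arrs = [np.asarray(r) for r in runs]
    n = arrs[0].shape[0]
    if any(a.shape != (n,) for a in arrs):
        raise ValueError("ragged run lengths")
    freq = np.zeros((n, n))
    for a in arrs:
        freq += a[:, None] == a[None, :]
    freq /= len(arrs)
    np.fill_diagonal(freq, 1.0)
    return freq


def build_network(
    freq: np.ndarray,
    threshold: float = 0.30,
    patient_ids: list[str] | None = None,
    node_attrs: dict[str, list] | None = None,
) -> ConsensusNetwork:
    """Keep pairs with co-assignment frequency >= threshold (closed bound)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    freq = np.asarray(freq, float)
    n = freq.shape[0]
    edges = [
        (i, j, float(freq[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if freq[i, j] >= threshold
    ]
    degrees = np.zeros(n, dtype=int)
    for i, j, _ in edges:
        degrees[i] += 1
        degrees[j] += 1
    return ConsensusNetwork(
        freq=freq,
        threshold=threshold,
        edges=edges,
        degrees=degrees,
        patient_ids=patient_ids or [],
        node_attrs=node_attrs or {},
    )


def run_consensus(
    data: list[PatientCellMatrix] | CountMatrix,
    k_topics: int,
    n_runs: int = 40,
    base_seed: int = 0,
    threshold: float = 0.30,
    hp: LDAHyperparams | None = None,
    vary_celltyping: bool = True,
    node_attrs: dict[str, list] | None = None,
) -> ConsensusNetwork:
    """Rerun the full workflow ``n_runs`` times and assemble the network.

    Run ``r`` uses seed ``base_seed + r`` for the sampler and, unless
    ``vary_celltyping`` is False (or the input is a count table, which has no
    cell-typing stage), for the K-means vocabulary as well — so the ensemble is
    reproducible as a unit from ``base_seed``.
    """
    if hp is None:
        hp = LDAHyperparams(K=k_topics)
    runs = []
    for r in range(n_runs):
        seed = base_seed + r
        res = double_cluster(
            data,
            k_topics,
            hp=replace(hp, seed=seed),
            celltyping_seed=seed if vary_celltyping else base_seed,
        )
        runs.append(res.patient_assignments)
    freq = coassignment_matrix(runs)
    ids = (
        data.patient_ids
        if isinstance(data, CountMatrix)
        else [p.patient_id for p in data]
    )
    return build_network(
        freq, threshold=threshold, patient_ids=list(ids), node_attrs=node_attrs
    )


def write_graphml(net: ConsensusNetwork, path: str | Path) -> None:
    nx.write_graphml(net.to_networkx(), str(path))


def write_edge_list(net: ConsensusNetwork, path: str | Path) -> None:
    ids = net.patient_ids or [str(i) for i in range(net.freq.shape[0])]
    pd.DataFrame(
        [(ids[i], ids[j], w) for i, j, w in net.edges],
        columns=["patient_i", "patient_j", "weight"],
    ).to_csv(path, sep="\t", index=False)


def write_freq_matrix(net: ConsensusNetwork, path: str | Path) -> None:
    ids = net.patient_ids or [str(i) for i in range(net.freq.shape[0])]
    pd.DataFrame(net.freq, index=ids, columns=ids).to_csv(path, sep="\t")
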