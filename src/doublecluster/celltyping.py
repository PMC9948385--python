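"""Shared cell-type vocabulary and patient count matrices.

Cells from all patients are pooled, standardized with one global Z-score, and
partitioned by K-means into ``W`` clusters (fixed to ``2**N`` for an N-marker
panel).  Each cluster is a "word" of the downstream topic model; assigning
every cell of every patient to its nearest centroid yields the patients x
cell-types count matrix — the corpus on which the topic model runs.  Count
tables produced elsewhere (e.g. bacterial genus abundances) enter through
:func:`read_count_table` and bypass this stage entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin

from .simulate import PatientCellMatrix

__all__ = [
    "CellTypeModel",
    "CountMatrix",
    "fit_cell_types",
    "assign_and_count",
    "read_count_table",
    "write_count_table",
]

# K-means settings used everywhere clustering on continuous data is needed:
# k-means++ init, 10 restarts, 300-iteration cap, tol 1e-4, seeded.
KMEANS_KWARGS = dict(init="k-means++", n_init=10, max_iter=300, tol=1e-4)


@dataclass
class CellTypeModel:
    """Pooled Z-score parameters plus K-means centroids in standardized space."""

    marker_means: np.ndarray
    marker_stds: np.ndarray
    centroids: np.ndarray
    W: int

    def __post_init__(self) -> None:
        self.marker_means = np.asarray(self.marker_means, float)
        self.marker_stds = np.asarray(self.marker_stds, float)
        self.centroids = np.asarray(self.centroids, float)
        if np.any(self.marker_stds <= 0):
            raise ValueError("marker_stds must all be positive")
        if self.centroids.shape[0] != self.W:
            raise ValueError("centroids must have exactly W rows")

    def standardize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, float)
        if values.shape[1] != self.marker_means.shape[0]:
            raise ValueError(
                f"marker dimension mismatch: model has {self.marker_means.shape[0]} "
                f"markers, data has {values.shape[1]}"
            )
        return (values - self.marker_means) / self.marker_stds

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) cluster ids; ties go to the lowest index."""
        return pairwise_distances_argmin(self.standardize(values), self.centroids)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "marker_means": self.marker_means.tolist(),
                    "marker_stds": self.marker_stds.tolist(),
                    "centroids": self.centroids.tolist(),
                    "W": int(self.W),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CellTypeModel":
        d = json.loads(Path(path).read_text())
        return cls(
            marker_means=np.array(d["marker_means"]),
            marker_stds=np.array(d["marker_stds"]),
            centroids=np.array(d["centroids"]),
            W=int(d["W"]),
        )


@dataclass
class CountMatrix:
    """Patients x cell-types (documents x words) nonnegative integer counts."""

    counts: np.ndarray
    patient_ids: list[str]
    W: int
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("not a count table: non-integer entries")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("not a count table: negative entries")
        self.counts = counts.astype(np.int64)
        if counts.shape[1] != self.W:
            raise ValueError("counts must have exactly W columns")
        if len(self.patient_ids) != counts.shape[0]:
            raise ValueError("one patient id per row required")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicated patient IDs")
        if not self.feature_names:
            self.feature_names = [f"ct{w}" for w in range(self.W)]

    @property
    def n_patients(self) -> int:
        return self.counts.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset(self, idx: np.ndarray) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            counts=self.counts[idx],
            patient_ids=[self.patient_ids[i] for i in idx],
            W=self.W,
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.feature_names,
        )


def fit_cell_types(
    cohort: list[PatientCellMatrix], W: int, seed: int = 0
) -> CellTypeModel:
    """Pool all patients' cells, Z-score, and K-means into ``W`` cell types.

    Standardization parameters are computed on the concatenation of every
    patient's cells (pooled-global scope) and reused for any later assignment,
    keeping the vocabulary transferable across patients.
    """
    if not cohort:
        raise ValueError("empty cohort")
    pooled = np.concatenate([p.values for p in cohort], axis=0)
    if pooled.shape[0] < W:
        raise ValueError(f"pooled cell count {pooled.shape[0]} < W={W}")
    means = pooled.mean(axis=0)
    stds = pooled.std(axis=0)
    if np.any(stds == 0):
        bad = np.flatnonzero(stds == 0).tolist()
        raise ValueError(f"constant marker: column(s) {bad} have zero pooled variance")
    z = (pooled - means) / stds
    n_distinct = np.unique(z, axis=0).shape[0]
    if W > n_distinct:
        raise ValueError(
            f"W={W} exceeds the number of distinct pooled points ({n_distinct})"
        )
    km = KMeans(n_clusters=W, random_state=seed, **KMEANS_KWARGS).fit(z)
    return CellTypeModel(
        marker_means=means, marker_stds=stds, centroids=km.cluster_centers_, W=W
    )


def assign_and_count(
    cohort: list[PatientCellMatrix], model: CellTypeModel
) -> CountMatrix:
    """Assign every cell to its nearest cell-type centroid and count per patient.

    Row ``d`` of the result sums to patient ``d``'s cell count; clusters with no
    cells in a given patient contribute legitimate zero counts (the vocabulary
    stays fixed at ``W``).
    """
    rows = np.zeros((len(cohort), model.W), dtype=np.int64)
    for d, patient in enumerate(cohort):
        labels = model.assign(patient.values)
        rows[d] = np.bincount(labels, minlength=model.W)
    return CountMatrix(
        counts=rows, patient_ids=[p.patient_id for p in cohort], W=model.W
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a patients x features count table (CSV/TSV, first column = IDs)."""
    df = _read_table(path)
    if df.index.duplicated().any():
        raise ValueError("duplicated patient IDs in count table")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("not a count table: non-numeric entries")
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        raise ValueError("not a count table: entries must be nonnegative integers")
    return CountMatrix(
        counts=values.astype(np.int64),
        patient_ids=[str(i) for i in df.index],
        W=df.shape[1],
        feature_names=[str(c) for c in df.columns],
    )


def write_count_table(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    counts.to_frame().to_csv(path, sep=sep)
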