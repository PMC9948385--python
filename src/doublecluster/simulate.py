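"""Synthetic flow-cytometry cohort generator.

The generator emulates the structure of a gated cytometry experiment: each of
``N`` fluorescent markers behaves as a two-component Gaussian mixture (a "low"
and a "high" expression state with a shared standard deviation), so a cell's
discrete phenotype is an ``N``-bit code and there are ``W = 2**N`` possible
cell types.  A patient class is a probability vector over those ``W`` cell
types; patients of a class draw their cells i.i.d. from the class vector and
the continuous marker values conditional on the drawn type.  The single knob
``distance`` sets the pairwise Euclidean distance between class vectors and
therefore the difficulty of the downstream stratification problem, while
``sigma`` controls how well the marker mixture components separate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import hadamard, helmert

__all__ = [
    "CohortSpec",
    "PhenotypeVector",
    "PatientCellMatrix",
    "make_phenotype_vectors",
    "simulate_patient",
    "simulate_cohort",
    "type_bit_codes",
]


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    Parameters
    ----------
    n_markers
        Number of fluorescent markers ``N``; the cell-type vocabulary has
        ``W = 2**N`` entries.
    n_phenotypes
        Number of patient classes.
    patients_per_phenotype
        Balanced class size (default 50 subjects per phenotype).
    cells_per_patient
        Number of cells measured per patient (default ``10_000``).
    mu_low, mu_high
        Means of the negative/positive marker mixture components.
    sigma
        Shared standard deviation of both components; the robustness knob.
    distance
        Target pairwise Euclidean distance between class probability vectors.
    seed
        Root seed; the cohort is a pure function of this spec.
    """

    n_markers: int
    n_phenotypes: int = 2
    patients_per_phenotype: int = 50
    cells_per_patient: int = 10_000
    mu_low: float = 0.0
    mu_high: float = 1.0
    sigma: float = 0.25
    distance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be a positive integer")
        if self.n_phenotypes < 1:
            raise ValueError("n_phenotypes must be a positive integer")
        if self.patients_per_phenotype < 1:
            raise ValueError("patients_per_phenotype must be positive")
        if self.cells_per_patient < 1:
            raise ValueError("cells_per_patient must be positive")
        if not self.mu_high > self.mu_low:
            raise ValueError("mu_high must exceed mu_low")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.distance < 0:
            raise ValueError("distance must be nonnegative")

    @property
    def W(self) -> int:
        """Vocabulary size, always derived as ``2**n_markers``."""
        return 2**self.n_markers

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        """Load a spec from a JSON or YAML config mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PhenotypeVector:
    """Probability distribution of one patient class over the W cell types."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(p < 0):
            raise ValueError("probs must be entrywise nonnegative")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("probs must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass
class PatientCellMatrix:
    """One patient's cells x markers continuous measurements.

    ``true_cell_types`` and ``true_phenotype`` carry the simulator's ground
    truth and are absent for real data.
    """

    patient_id: str
    values: np.ndarray
    true_cell_types: np.ndarray | None = None
    true_phenotype: int | None = None
    marker_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        if self.true_cell_types is not None:
            self.true_cell_types = np.asarray(self.true_cell_types, dtype=int)
            if self.true_cell_types.shape[0] != self.values.shape[0]:
                raise ValueError("true_cell_types must have one entry per cell")
        if not self.marker_names:
            self.marker_names = [f"M{j}" for j in range(self.values.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


def type_bit_codes(n_markers: int) -> np.ndarray:
    """(W, N) matrix of marker states: bit j of type t is ``(t >> j) & 1``."""
    w = 2**n_markers
    t = np.arange(w)[:, None]
    return (t >> np.arange(n_markers)[None, :]) & 1


def _signatures(n_phenotypes: int, w: int) -> np.ndarray:
    """Zero-sum, unit-norm, mutually orthogonal signature vectors.

    For a power-of-two vocabulary these are scaled Hadamard rows (entries of
    equal magnitude, so every cell type is perturbed symmetrically); other
    sizes fall back to Helmert rows, which are likewise orthonormal and
    zero-sum.
    """
    if n_phenotypes > w - 1:
        raise ValueError(
            f"cannot construct {n_phenotypes} equidistant class vectors over "
            f"{w} cell types: at most {w - 1} orthogonal zero-sum signatures exist"
        )
    if w & (w - 1) == 0:  # power of two
        rows = hadamard(w)[1 : n_phenotypes + 1] / np.sqrt(w)
    else:
        rows = helmert(w, full=False)[:n_phenotypes]
    return rows.astype(float)


def make_phenotype_vectors(
    n_phenotypes: int, W: int, distance: float, seed: int = 0
) -> list[PhenotypeVector]:
    """Construct class probability vectors with equal pairwise distances.

    Each class vector is ``clip(u + (distance/sqrt(2)) * h_c, 0)`` renormalized,
    where ``u`` is the uniform vector over ``W`` cell types and the ``h_c`` are
    orthogonal zero-sum unit signatures; orthogonality makes every pairwise
    Euclidean distance equal to ``distance`` exactly when no clipping occurs.
    The seed permutes which cell types each signature enriches, leaving all
    distances intact.

    Raises
    ------
    ValueError
        If ``W < n_phenotypes``, if no signature set exists, or if ``distance``
        is so large that clipping distorts the achieved pairwise distances by
        more than 10% of the target.
    """
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    if W < n_phenotypes:
        raise ValueError("W must be at least n_phenotypes")
    if distance < 0:
        raise ValueError("distance must be nonnegative")

    u = np.full(W, 1.0 / W)
    if distance == 0 or n_phenotypes == 1:
        return [PhenotypeVector(u.copy()) for _ in range(n_phenotypes)]

    sig = _signatures(n_phenotypes, W)
    perm = np.random.default_rng(seed).permutation(W)
    sig = sig[:, perm]

    raw = u[None, :] + (distance / np.sqrt(2.0)) * sig
    clipped = np.any(raw < -1e-12)
    vecs = np.clip(raw, 0.0, None)
    vecs /= vecs.sum(axis=1, keepdims=True)

    if clipped:
        from scipy.spatial.distance import pdist

        achieved = pdist(vecs)
        if np.any(np.abs(achieved - distance) > 0.10 * distance):
            raise ValueError(
                f"distance not achievable at this W: target {distance}, "
                f"achieved pairwise distances {np.round(achieved, 4)}"
            )
    return [PhenotypeVector(v) for v in vecs]


def simulate_patient(
    vec: PhenotypeVector,
    spec: CohortSpec,
    patient_id: str,
    rng_stream: np.random.Generator,
) -> PatientCellMatrix:
    """Draw one patient: cell types i.i.d. from ``vec``, markers conditional.

    Cell type ``t`` is decoded as an N-bit binary code; marker ``j`` is drawn
    ``Normal(mu_high, sigma)`` when bit ``j`` of ``t`` is 1 and
    ``Normal(mu_low, sigma)`` otherwise.
    """
    probs = np.asarray(vec.probs if isinstance(vec, PhenotypeVector) else vec, float)
    if probs.shape[0] != spec.W:
        raise ValueError(f"phenotype vector length {probs.shape[0]} != W={spec.W}")
    if abs(probs.sum() - 1.0) > 1e-8 or np.any(probs < 0):
        raise ValueError("phenotype vector is not a probability distribution")

    types = rng_stream.choice(spec.W, size=spec.cells_per_patient, p=probs)
    bits = type_bit_codes(spec.n_markers)[types]  # (cells, N)
    means = spec.mu_low + bits * (spec.mu_high - spec.mu_low)
    values = rng_stream.normal(loc=means, scale=spec.sigma)
    return PatientCellMatrix(
        patient_id=patient_id,
        values=values,
        true_cell_types=types,
    )


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientCellMatrix], np.ndarray, list[PhenotypeVector]]:
    """Generate a balanced cohort: patients, true class labels, class vectors.

    The cohort is a pure function of ``spec`` (including ``spec.seed``).  Each
    patient gets an independent substream spawned from the root seed, so
    patient ``i``'s cells do not depend on how many other patients exist.
    """
    vectors = make_phenotype_vectors(
        spec.n_phenotypes, spec.W, spec.distance, seed=spec.seed
    )
    n_patients = spec.n_phenotypes * spec.patients_per_phenotype
    children = np.random.SeedSequence(spec.seed).spawn(n_patients)

    patients: list[PatientCellMatrix] = []
    labels = np.repeat(np.arange(spec.n_phenotypes), spec.patients_per_phenotype)
    for i, label in enumerate(labels):
        rng = np.random.default_rng(children[i])
        p = simulate_patient(vectors[label], spec, patient_id=f"P{i:04d}", rng_stream=rng)
        p.true_phenotype = int(label)
        patients.append(p)
    return patients, labels, vectors
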