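"""Plain-text artifact I/O: cohorts, manifests, models, results.

A simulated (or externally prepared) cohort on disk is one CSV per patient
(cells x markers, header = marker names, no index column), a manifest TSV
listing ``patient_id, phenotype_label, file`` and, for simulated cohorts, a
ground-truth TSV of per-cell types.  Fitted models and results serialize to
JSON/TSV so downstream graph and stats tools can pick them up.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lda import TopicModel
from .pipeline import DoubleClusteringResult
from .simulate import PatientCellMatrix

__all__ = [
    "write_cohort",
    "read_cohort",
    "load_config",
    "write_topic_model",
    "read_topic_model",
    "write_result",
]

MANIFEST_NAME = "manifest.tsv"
TRUTH_NAME = "true_cell_types.tsv"


def write_cohort(
    outdir: str | Path,
    cohort: list[PatientCellMatrix],
    labels=None,
) -> Path:
    """Write one CSV per patient plus a manifest TSV; returns the manifest path.

    When ground-truth cell types are present they are written to a single
    long-format TSV (patient_id, cell_index, cell_type).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_frames = []
    for i, p in enumerate(cohort):
        fname = f"{p.patient_id}.csv"
        pd.DataFrame(p.values, columns=p.marker_names).to_csv(
            outdir / fname, index=False
        )
        label = (
            labels[i]
            if labels is not None
            else (p.true_phenotype if p.true_phenotype is not None else "")
        )
        rows.append({"patient_id": p.patient_id, "phenotype_label": label, "file": fname})
        if p.true_cell_types is not None:
            truth_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": p.patient_id,
                        "cell_index": np.arange(p.n_cells),
                        "cell_type": p.true_cell_types,
                    }
                )
            )
    manifest = outdir / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth_frames:
        pd.concat(truth_frames).to_csv(outdir / TRUTH_NAME, sep="\t", index=False)
    return manifest


def read_cohort(
    manifest_path: str | Path,
) -> tuple[list[PatientCellMatrix], np.ndarray | None]:
    """Read a cohort from a manifest TSV; returns (patients, labels or None)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    mf = pd.read_csv(manifest_path, sep="\t")
    patients = []
    for _, row in mf.iterrows():
        df = pd.read_csv(base / row["file"])
        patients.append(
            PatientCellMatrix(
                patient_id=str(row["patient_id"]),
                values=df.to_numpy(float),
                marker_names=[str(c) for c in df.columns],
            )
        )
    labels = None
    if "phenotype_label" in mf.columns and mf["phenotype_label"].notna().all():
        labels = mf["phenotype_label"].to_numpy()
    return patients, labels


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def write_topic_model(model: TopicModel, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "theta": model.theta.tolist(),
        "phi": model.phi.tolist(),
        "loglik_trace": (
            model.loglik_trace.tolist() if model.loglik_trace is not None else None
        ),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload))


def read_topic_model(path: str | Path) -> TopicModel:
    d = json.loads(Path(path).read_text())
    trace = d.get("loglik_trace")
    return TopicModel(
        theta=np.array(d["theta"]),
        phi=np.array(d["phi"]),
        loglik_trace=np.array(trace) if trace is not None else None,
    )


def write_result(result: DoubleClusteringResult, outdir: str | Path) -> None:
    """Write assignments, theta, and P(topic|cell type) TSVs plus a result JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = result.counts.patient_ids
    k = result.theta.shape[1]
    pd.DataFrame(
        {"patient_id": ids, "cluster": result.patient_assignments}
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.theta, index=pd.Index(ids, name="patient_id"),
        columns=[f"topic{j}" for j in range(k)],
    ).to_csv(outdir / "theta.tsv", sep="\t")
    pd.DataFrame(
        result.celltype_topic,
        index=pd.Index(result.counts.feature_names, name="cell_type"),
        columns=[f"topic{j}" for j in range(k)],
    ).to_csv(outdir / "celltype_topic.tsv", sep="\t")
    (outdir / "result.json").write_text(json.dumps(result.config_echo))
    if result.cell_model is not None:
        result.cell_model.to_json(outdir / "cell_model.json")
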