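"""Cluster patients directly from an abundance count table.

Pre-made patient x feature counts (e.g. a bacterial genus table) skip the
cell-typing stage: patients are documents, features are words.  A small
synthetic table with two obvious patient groups is written, read back through
the standard table reader, and clustered with K=2 topics.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from doublecluster import double_cluster, read_count_table

rng = np.random.default_rng(0)
genera = ["Faecalibacterium", "Roseburia", "Blautia", "Veillonella", "Haemophilus"]
# group A loads on the first genera, group B on the last
rows = np.vstack(
    [rng.multinomial(300, [0.4, 0.3, 0.2, 0.05, 0.05]) for _ in range(8)]
    + [rng.multinomial(300, [0.05, 0.05, 0.2, 0.3, 0.4]) for _ in range(8)]
)
table = pd.DataFrame(rows, index=[f"S{i:02d}" for i in range(16)], columns=genera)
table.index.name = "patient_id"

path = Path(tempfile.mkdtemp()) / "genus_counts.tsv"
table.to_csv(path, sep="\t")
counts = read_count_table(path)
print(f"read {counts.n_patients} patients x {counts.W} genera from {path.name}")

result = double_cluster(counts, k_topics=2, lda_seed=1)
print("cell_model is None (no cell-typing stage):", result.cell_model is None)
print("patient clusters:", result.patient_assignments)

ct = pd.DataFrame(result.celltype_topic, index=genera,
                  columns=["topic0", "topic1"]).round(3)
print("\nP(topic | genus):")
print(ct)
print("-> genera with a row near 1.0 in one column characterize that cluster.")
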