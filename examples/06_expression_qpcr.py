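"""Expression analytics end to end: FPKM, the 2-fold differential filter,
hierarchical clustering, a qPCR fold change with replicate statistics, and
a duplicate-pair fate call."""

import pandas as pd

from tlpfam import (
    cluster_genes,
    ddct_fold,
    differential_filter,
    duplicate_fate,
    fpkm,
)
from tlpfam.expression import QpcrTable
from tlpfam.synthetic import generate_expression

genes = [f"gene{i}" for i in range(12)]
counts, lengths, totals, truth = generate_expression(genes, noise_sd=0.0, seed=6)
matrix = fpkm(counts, lengths, totals)

calls = differential_filter(matrix, "control", list(truth.conditions[1:]))
flagged = [c.gene_id for c in calls if c.flagged]
print(f"{len(flagged)}/{len(genes)} genes differential (>= 2-fold): {flagged}")

labels = cluster_genes(matrix, k=4).labels
print("cluster assignments:", labels)

# qPCR: treated dCt one cycle below control -> 2-fold up-regulation
rows = pd.DataFrame(
    [
        ("gene0", "control", r, 24.0 + d, 21.0)
        for r, d in enumerate((0.0, 0.1, -0.1))
    ]
    + [
        ("gene0", "salt_12h", r, 23.0 + d, 21.0)
        for r, d in enumerate((0.0, 0.1, -0.1))
    ],
    columns=["gene_id", "condition", "replicate", "ct_target", "ct_reference"],
)
(fc,) = ddct_fold(QpcrTable.from_dataframe(rows, "control"))
print(f"\nqPCR gene0 salt_12h: fold {fc.fold:.2f} +/- {fc.sd:.2f}, "
      f"p = {fc.p_value:.4f} ({fc.significance})")

fate = duplicate_fate(matrix, ("gene0", "gene4"))
print(f"\nduplicate pair gene0/gene4: {fate.fate} "
      f"(r = {fate.correlation if fate.correlation is None else round(fate.correlation, 2)})")
print("\nThe filter reproduces the planted fold structure exactly at zero "
      "noise; the fate call reads conserved vs diverged vs silenced "
      "expression of a duplicated pair.")
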