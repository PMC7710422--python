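"""Tumor-vs-normal differential expression on one synthetic cancer type.

HIF3A and EPAS1 are planted two-fold down, HIF1A ~1.5-fold down and ARNT
~1.5-fold up; the table shows the estimated log2 fold change, the BH-
adjusted p-value, and the up/down/ns call at the FC >= 2 / FDR < 0.05
gates.
"""

import panlandscape as pl

config = pl.CohortConfig(
    cancer_types=("LIHC",), n_background_genes=100,
    n_tumor=25, n_normal=25, n_cell_lines=10, n_drugs=3, seed=2,
)
bundle = pl.generate_cohort(config)
counts = bundle.counts["LIHC"]
split = pl.match_tumor_normal(counts)

result = pl.differential_expression(counts, split.tumors, split.normals, "LIHC")
family = result[result["gene"].isin(pl.TARGET_GENES)]
print(family.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\n'up'/'down' means at least a two-fold change (|log2FC| >= 1) at "
    "FDR < 0.05; background genes carry no planted change and stay 'ns'."
)
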