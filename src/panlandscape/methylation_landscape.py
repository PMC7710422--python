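"""Promoter-methylation landscape: differential methylation and
methylation-expression correlation.

Methylation arrives as gene-level beta values in [0, 1] (promoter probes
already collapsed, e.g. by their mean — that pre-step is upstream of this
module). Tumor-vs-normal differences use Student's pooled-variance t test
on the betas with BH adjustment per cancer; a gene is hyper- (hypo-)
methylated when the tumor-minus-normal delta beta is positive (negative)
at FDR < 0.05. Methylation and expression are correlated by Spearman on
barcode-matched samples only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneSampleMatrix
from .stats import benjamini_hochberg, spearman

__all__ = ["differential_methylation", "methylation_expression_correlation"]

DIFF_COLUMNS = [
    "gene", "cancer_type", "mean_beta_tumor", "mean_beta_normal",
    "delta_beta", "p_value", "fdr", "direction",
]

CORR_COLUMNS = ["gene", "cancer_type", "rho", "p_value", "fdr", "n"]


def differential_methylation(
    beta: GeneSampleMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    cancer_type: str = "",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    if beta.semantics != "beta":
        raise ValueError("differential methylation requires beta semantics")
    tumor_samples, normal_samples = list(tumor_samples), list(normal_samples)
    if len(tumor_samples) < 3 or len(normal_samples) < 3:
        raise ValueError(
            f"need >= 3 samples per group, have {len(tumor_samples)} tumor / "
            f"{len(normal_samples)} normal"
        )
    tum = beta.values.loc[:, tumor_samples].to_numpy()
    nor = beta.values.loc[:, normal_samples].to_numpy()
    mean_t, mean_n = tum.mean(axis=1), nor.mean(axis=1)
    res = sps.ttest_ind(tum, nor, axis=1, equal_var=True)  # Student's pooled t
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(pvals)
    pvals[degenerate & np.isclose(mean_t, mean_n)] = 1.0
    pvals[degenerate & ~np.isclose(mean_t, mean_n)] = 0.0
    fdr = benjamini_hochberg(pvals)
    delta = mean_t - mean_n
    direction = np.where(
        (fdr < fdr_threshold) & (delta > 0),
        "hyper",
        np.where((fdr < fdr_threshold) & (delta < 0), "hypo", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": beta.genes,
            "cancer_type": cancer_type,
            "mean_beta_tumor": mean_t,
            "mean_beta_normal": mean_n,
            "delta_beta": delta,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
        },
        columns=DIFF_COLUMNS,
    )


def methylation_expression_correlation(
    beta: GeneSampleMatrix,
    expression: GeneSampleMatrix,
    cancer_type: str = "",
) -> pd.DataFrame:
    """Spearman between beta and expression on barcode-matched samples.

    Matching is the symmetric intersection of the two sample sets. Genes
    with < 3 matched complete pairs yield a missing-result row; if the two
    matrices share no samples at all, every gene is a missing-result row.
    """
    shared = beta.values.columns.intersection(expression.values.columns)
    rows = []
    for gene in beta.genes:
        if gene not in expression.values.index:
            continue
        if len(shared) < 3:
            rows.append(
                {"gene": gene, "cancer_type": cancer_type, "rho": np.nan,
                 "p_value": np.nan, "n": len(shared)}
            )
            continue
        x = beta.values.loc[gene, shared].to_numpy()
        y = expression.values.loc[gene, shared].to_numpy()
        rho, p = spearman(x, y)
        n = int((~(np.isnan(x) | np.isnan(y))).sum())
        rows.append(
            {"gene": gene, "cancer_type": cancer_type, "rho": rho, "p_value": p, "n": n}
        )
    out = pd.DataFrame(rows, columns=[c for c in CORR_COLUMNS if c != "fdr"])
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out[CORR_COLUMNS]
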