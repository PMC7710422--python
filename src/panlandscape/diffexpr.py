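"""Tumor-vs-normal differential expression with fold-change and FDR gates.

Counts are normalized with median-of-ratios size factors, the fold change
is computed on group means of normalized counts (pseudocount 0.5), and the
p-value comes from a Welch two-sample t test on log2(normalized + 1).
Within each cancer type, p-values are Benjamini-Hochberg adjusted across
the tested genes, and a gene is called up (down) when log2FC >= 1
(<= -1) — i.e. a two-fold change, boundary inclusive — with FDR < 0.05.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneSampleMatrix
from .stats import benjamini_hochberg

__all__ = ["size_factors", "differential_expression", "benjamini_hochberg"]

DE_COLUMNS = ["gene", "cancer_type", "log2_fc", "p_value", "fdr", "status"]


def size_factors(counts: GeneSampleMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, the factor is the median over reference genes of
    count_gj / geomean_g, where the reference set is every gene with a
    positive count in all samples (so the geometric mean is positive).
    Identical samples get identical factors.
    """
    if counts.semantics != "raw_count":
        raise ValueError("size factors are defined on raw_count matrices")
    arr = counts.values.to_numpy()
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "every gene has a zero count in some sample; no median-of-ratios "
            "reference exists — consider a pseudo-reference (e.g. +1 pseudocount)"
        )
    ref = arr[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def differential_expression(
    counts: GeneSampleMatrix,
    tumor_samples: Sequence[str],
    normal_samples: Sequence[str],
    cancer_type: str = "",
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential expression for one cancer.

    Returns a frame with columns gene, cancer_type, log2_fc, p_value, fdr,
    status; status is 'up'/'down'/'ns' per the fold-change and FDR gates
    (|log2FC| >= log2(fc_threshold), boundary inclusive, and
    fdr < fdr_threshold).
    """
    tumor_samples = list(tumor_samples)
    normal_samples = list(normal_samples)
    if len(tumor_samples) < 3 or len(normal_samples) < 3:
        raise ValueError(
            f"need >= 3 samples per group, have {len(tumor_samples)} tumor / "
            f"{len(normal_samples)} normal"
        )
    factors = size_factors(counts)
    norm = counts.values.div(factors, axis=1)
    tum = norm.loc[:, tumor_samples].to_numpy()
    nor = norm.loc[:, normal_samples].to_numpy()

    log2_fc = np.log2((tum.mean(axis=1) + 0.5) / (nor.mean(axis=1) + 0.5))

    log_tum = np.log2(tum + 1.0)
    log_nor = np.log2(nor + 1.0)
    res = sps.ttest_ind(log_tum, log_nor, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p = 1, else p -> 0
    degenerate = np.isnan(pvals)
    equal_means = np.isclose(log_tum.mean(axis=1), log_nor.mean(axis=1))
    pvals[degenerate & equal_means] = 1.0
    pvals[degenerate & ~equal_means] = 0.0

    fdr = benjamini_hochberg(pvals)
    lfc_gate = np.log2(fc_threshold)
    status = np.where(
        (fdr < fdr_threshold) & (log2_fc >= lfc_gate),
        "up",
        np.where((fdr < fdr_threshold) & (log2_fc <= -lfc_gate), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": counts.genes,
            "cancer_type": cancer_type,
            "log2_fc": log2_fc,
            "p_value": pvals,
            "fdr": fdr,
            "status": status,
        },
        columns=DE_COLUMNS,
    )
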