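"""Copy-number event landscape: event classification, percentages, and
CNV-expression correlation.

Gene-level thresholded calls use the conventional five-level coding:
-2 homozygous deletion, -1 heterozygous deletion, 0 neutral,
+1 heterozygous amplification, +2 homozygous amplification (the event
touches one vs both chromosome copies). Per gene and cancer the four event
percentages are reported, and a gene is displayed only when its total CNV
burden strictly exceeds the display threshold (default 5%). CNV calls are
correlated with expression by Spearman (average ranks for ties), FDR per
cancer.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import GeneSampleMatrix
from .stats import benjamini_hochberg, spearman

__all__ = ["classify_call", "event_percentages", "cnv_expression_correlation"]

_CALL_CATEGORY = {
    -2: "homo_del",
    -1: "hete_del",
    0: "none",
    1: "hete_amp",
    2: "homo_amp",
}

PROFILE_COLUMNS = [
    "gene", "cancer_type", "pct_hete_amp", "pct_hete_del",
    "pct_homo_amp", "pct_homo_del", "n_samples", "displayed",
]

CORRELATION_COLUMNS = ["gene", "cancer_type", "rho", "p_value", "fdr", "n"]


def classify_call(call: int) -> str:
    """Map a thresholded call to its event category."""
    call = int(call)
    if call not in _CALL_CATEGORY:
        raise ValueError(f"CNV call {call} outside {{-2,-1,0,1,2}}")
    return _CALL_CATEGORY[call]


def event_percentages(
    calls: GeneSampleMatrix,
    cancer_type: str = "",
    display_threshold_pct: float = 5.0,
    per_category: bool = False,
) -> pd.DataFrame:
    """Per-gene percentages of the four CNV event categories.

    ``displayed`` is True when the union of the four event percentages is
    strictly greater than ``display_threshold_pct`` (exactly 5% is not
    displayed); with ``per_category`` the rule instead keeps a gene when
    any single category exceeds the threshold.
    """
    if calls.semantics != "cnv_call":
        raise ValueError("event percentages require cnv_call semantics")
    rows = []
    for gene in calls.genes:
        vals = calls.values.loc[gene].dropna()
        n = len(vals)
        if n == 0:
            raise ValueError(f"gene {gene!r} has no CNV calls")
        pct = {
            cat: 100.0 * (vals == code).sum() / n
            for code, cat in _CALL_CATEGORY.items()
            if cat != "none"
        }
        if per_category:
            displayed = any(v > display_threshold_pct for v in pct.values())
        else:
            displayed = sum(pct.values()) > display_threshold_pct
        rows.append(
            {
                "gene": gene,
                "cancer_type": cancer_type,
                "pct_hete_amp": pct["hete_amp"],
                "pct_hete_del": pct["hete_del"],
                "pct_homo_amp": pct["homo_amp"],
                "pct_homo_del": pct["homo_del"],
                "n_samples": n,
                "displayed": displayed,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def cnv_expression_correlation(
    calls: GeneSampleMatrix,
    expression: GeneSampleMatrix,
    cancer_type: str = "",
) -> pd.DataFrame:
    """Spearman correlation between the integer call and expression per gene.

    Samples are matched by shared barcode; genes must be present in both
    matrices. Degenerate genes (constant calls, < 3 complete pairs) yield a
    missing-result row (NaN rho/p/fdr) rather than an error.
    """
    shared = calls.values.columns.intersection(expression.values.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, have {len(shared)}")
    rows = []
    for gene in calls.genes:
        if gene not in expression.values.index:
            continue
        x = calls.values.loc[gene, shared].to_numpy()
        y = expression.values.loc[gene, shared].to_numpy()
        rho, p = spearman(x, y)
        n = int((~(pd.isna(x) | pd.isna(y))).sum())
        rows.append(
            {"gene": gene, "cancer_type": cancer_type, "rho": rho, "p_value": p, "n": n}
        )
    out = pd.DataFrame(rows, columns=[c for c in CORRELATION_COLUMNS if c != "fdr"])
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out[CORRELATION_COLUMNS]
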