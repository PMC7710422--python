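"""Median-split overall-survival association per gene per cancer.

Samples are split at the gene's median expression (ties go low, matching
the pathway-activity stage), and the two groups are compared with the
standard two-group log-rank test: at each distinct event time the expected
death count per group follows the hypergeometric model, and the statistic
is (O - E)^2 / V for the high group, chi-square with 1 df. The sign of the
high group's observed-minus-expected death count gives the verdict: more
deaths than expected under high expression is 'unfavorable', fewer is
'favorable', and p >= alpha is 'ns'. This is deliberately a
non-parametric stand-in for a hazard model: no iterative fitting, and the
direction plays the role of a hazard-ratio sign.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from scipy import stats as sps

from .io_formats import GeneSampleMatrix
from .stats import benjamini_hochberg

__all__ = ["logrank_statistic", "logrank_median_split", "survival_associations"]

ASSOC_COLUMNS = [
    "gene", "cancer_type", "logrank_chi2", "p_value",
    "o_minus_e_high", "verdict",
]


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, in_high: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-square and the high group's O - E.

    Accumulates observed and (hypergeometric) expected deaths over the
    distinct event times; censored records leave the risk set just after
    their time (ties between a death and a censoring keep the censored
    subject at risk for that death time).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    in_high = np.asarray(in_high, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_high = (at_risk & in_high).sum()
        deaths = ((time == t) & (event == 1)).sum()
        deaths_high = ((time == t) & (event == 1) & in_high).sum()
        expected_high = deaths * n_high / n
        o_minus_e += deaths_high - expected_high
        if n > 1:
            var += (
                deaths * (n_high / n) * (1 - n_high / n) * (n - deaths) / (n - 1)
            )
    if var == 0:
        return 0.0, float(o_minus_e)
    chi2 = o_minus_e**2 / var
    return float(chi2), float(o_minus_e)


def logrank_median_split(
    expression: GeneSampleMatrix,
    survival: pd.DataFrame,
    gene: str,
    cancer_type: str = "",
    alpha: float = 0.05,
) -> dict:
    """Log-rank association of one gene's median-split expression with
    overall survival; returns a record dict (see ASSOC_COLUMNS)."""
    if not {"sample", "time", "event"} <= set(survival.columns):
        raise ValueError("survival table needs columns sample, time, event")
    if (survival["time"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not survival["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    surv = survival.set_index("sample")
    shared = expression.values.columns.intersection(surv.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 samples with expression and survival, have {len(shared)}")
    expr = expression.values.loc[gene, shared]
    time = surv.loc[shared, "time"].to_numpy(dtype=float)
    event = surv.loc[shared, "event"].to_numpy(dtype=int)
    if event.sum() == 0:
        warnings.warn(f"all samples censored for {gene!r}; verdict ns", stacklevel=2)
        return _record(gene, cancer_type, np.nan, np.nan, np.nan, "ns")
    in_high = (expr > expr.median()).to_numpy()
    if in_high.sum() == 0 or (~in_high).sum() == 0:
        warnings.warn(f"median split emptied a group for {gene!r}; skipped", stacklevel=2)
        return _record(gene, cancer_type, np.nan, np.nan, np.nan, "skipped")
    chi2, o_minus_e = logrank_statistic(time, event, in_high)
    p = float(sps.chi2.sf(chi2, df=1))
    if p < alpha and o_minus_e > 0:
        verdict = "unfavorable"
    elif p < alpha and o_minus_e < 0:
        verdict = "favorable"
    else:
        verdict = "ns"
    return _record(gene, cancer_type, chi2, p, o_minus_e, verdict)


def _record(gene, cancer, chi2, p, ome, verdict) -> dict:
    return {
        "gene": gene,
        "cancer_type": cancer,
        "logrank_chi2": chi2,
        "p_value": p,
        "o_minus_e_high": ome,
        "verdict": verdict,
    }


def survival_associations(
    expression: GeneSampleMatrix,
    survival: pd.DataFrame,
    genes: Sequence[str] | None = None,
    cancer_type: str = "",
    alpha: float = 0.05,
    adjust_fdr: bool = False,
) -> pd.DataFrame:
    """Batch log-rank associations for many genes in one cancer.

    Per-gene calls are unadjusted by default (one call per gene, mirroring
    a per-gene prognostic panel); ``adjust_fdr=True`` applies BH across the
    genes and re-derives the verdicts from the adjusted values.
    """
    genes = list(genes) if genes is not None else expression.genes
    records = [
        logrank_median_split(expression, survival, g, cancer_type, alpha)
        for g in genes
    ]
    out = pd.DataFrame(records, columns=ASSOC_COLUMNS)
    if adjust_fdr:
        fdr = benjamini_hochberg(out["p_value"].to_numpy())
        out["fdr"] = fdr
        verdicts = []
        for i, row in out.iterrows():
            if np.isnan(fdr[i]) or fdr[i] >= alpha or row["verdict"] == "skipped":
                verdicts.append(row["verdict"] if row["verdict"] == "skipped" else "ns")
            else:
                verdicts.append("unfavorable" if row["o_minus_e_high"] > 0 else "favorable")
        out["verdict"] = verdicts
    return out
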