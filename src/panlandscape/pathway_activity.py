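"""RPPA pathway-activity scores and their association with gene expression.

The pathway activity score (PAS) of a sample is the sign-weighted mean of
normalized pathway-member protein levels: activating members count
positively, inhibitory members negatively. Protein levels are first
median-centered per component and scaled by the standard deviation across
patients. For each (gene, pathway, cancer) cell, samples are split at the
gene's median expression; a Student's t test on PAS between the high and
low halves, FDR-adjusted per cancer across all gene x pathway cells, calls
the pathway activated (PAS higher under high expression) or inhibited.
A gene is kept for the summary heatmap when it is functional (activated or
inhibited) in at least ``min_cancers`` cancer types (default 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GeneSampleMatrix
from .stats import benjamini_hochberg

__all__ = [
    "PathwayDefinition",
    "normalize_rppa",
    "pathway_score",
    "pas_association",
    "pas_associations",
    "pas_global_summary",
]

ASSOCIATION_COLUMNS = [
    "gene",
    "pathway",
    "cancer_type",
    "mean_pas_high",
    "mean_pas_low",
    "p_value",
    "fdr",
    "verdict",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway with signed member components.

    ``members`` maps component IDs to +1 (activating) or -1 (inhibitory).
    """

    name: str
    members: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")
        ids = [m for m, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pathway {self.name!r} has duplicate component IDs")
        if any(sign not in (1, -1) for _, sign in self.members):
            raise ValueError(f"pathway {self.name!r} has a sign outside {{+1, -1}}")


def normalize_rppa(protein: GeneSampleMatrix) -> GeneSampleMatrix:
    """Center each component on its median and scale by the patient std.

    out = (x - median) / std, both taken across patients per component,
    with the n-1 sample std. Zero-variance components are dropped with a
    warning. Applying the transform to its own output is a no-op (median 0,
    std 1 already).
    """
    if protein.values.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    values = protein.values
    med = values.median(axis=1)
    std = values.std(axis=1, ddof=1)
    keep = std > 0
    if not keep.all():
        dropped = values.index[~keep].tolist()
        warnings.warn(f"dropping zero-variance component(s): {dropped}", stacklevel=2)
    out = values.loc[keep].sub(med[keep], axis=0).div(std[keep], axis=0)
    return GeneSampleMatrix(out, "protein_level")


def pathway_score(normalized: GeneSampleMatrix, pathway: PathwayDefinition) -> pd.Series:
    """Per-sample PAS: mean over present members of sign * protein level."""
    present = [(m, s) for m, s in pathway.members if m in normalized.values.index]
    if not present:
        raise ValueError(f"no members of pathway {pathway.name!r} present in matrix")
    ids = [m for m, _ in present]
    signs = np.array([s for _, s in present], dtype=float)
    levels = normalized.values.loc[ids].to_numpy()
    pas = (signs[:, None] * levels).mean(axis=0)
    return pd.Series(pas, index=normalized.values.columns, name=pathway.name)


def _split_high_low(expr: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Median split; ties at the median go to the low group."""
    med = expr.median()
    high = (expr > med).to_numpy()
    return high, ~high


def pas_association(
    expression: pd.Series,
    pas: pd.Series,
    gene: str,
    pathway: str,
    cancer_type: str,
    fdr_threshold: float = 0.05,
) -> dict:
    """Single (gene, pathway) association without FDR adjustment.

    The returned record carries the raw p in both ``p_value`` and ``fdr``;
    use :func:`pas_associations` for FDR-adjusted batch tests.
    """
    shared = expression.index.intersection(pas.index)
    if len(shared) < 6:
        raise ValueError(
            f"need >= 6 samples with both expression and PAS, have {len(shared)}"
        )
    expr = expression.loc[shared]
    score = pas.loc[shared]
    high, low = _split_high_low(expr)
    if high.sum() == 0 or low.sum() == 0:
        warnings.warn(
            f"median split emptied a group for gene {gene!r}; association skipped",
            stacklevel=2,
        )
        return _record(gene, pathway, cancer_type, np.nan, np.nan, np.nan, np.nan)
    hi, lo = score[high], score[low]
    if np.ptp(score.to_numpy()) == 0:
        p = 1.0
    else:
        p = float(sps.ttest_ind(hi, lo, equal_var=True).pvalue)
        if np.isnan(p):
            p = 1.0
    rec = _record(gene, pathway, cancer_type, hi.mean(), lo.mean(), p, p)
    rec["verdict"] = _verdict(rec, fdr_threshold)
    return rec


def _record(gene, pathway, cancer, mh, ml, p, fdr) -> dict:
    return {
        "gene": gene,
        "pathway": pathway,
        "cancer_type": cancer,
        "mean_pas_high": mh,
        "mean_pas_low": ml,
        "p_value": p,
        "fdr": fdr,
        "verdict": "none",
    }


def _verdict(rec: dict, fdr_threshold: float) -> str:
    if np.isnan(rec["fdr"]) or rec["fdr"] >= fdr_threshold:
        return "none"
    if rec["mean_pas_high"] > rec["mean_pas_low"]:
        return "activation"
    if rec["mean_pas_high"] < rec["mean_pas_low"]:
        return "inhibition"
    return "none"


def pas_associations(
    expression: GeneSampleMatrix,
    rppa: GeneSampleMatrix,
    pathways: list[PathwayDefinition],
    cancer_type: str,
    genes: list[str] | None = None,
    fdr_threshold: float = 0.05,
    pre_normalized: bool = False,
) -> pd.DataFrame:
    """All gene x pathway associations for one cancer, BH-adjusted together.

    ``expression`` provides the grouping variable (any monotone scale);
    ``rppa`` the raw protein levels (normalized here unless
    ``pre_normalized``). FDR is controlled per cancer across every
    (gene, pathway) cell, mirroring one heatmap panel.
    """
    normalized = rppa if pre_normalized else normalize_rppa(rppa)
    shared = expression.values.columns.intersection(normalized.values.columns)
    if len(shared) < 6:
        raise ValueError(f"need >= 6 shared samples, have {len(shared)}")
    genes = list(genes) if genes is not None else expression.genes
    expr = expression.values.loc[genes, shared]
    pas = pd.DataFrame(
        {pw.name: pathway_score(normalized, pw).loc[shared] for pw in pathways}
    ).T  # pathways x samples

    records: list[dict] = []
    pas_arr = pas.to_numpy()
    for gene in genes:
        high, low = _split_high_low(expr.loc[gene])
        if high.sum() == 0 or low.sum() == 0:
            warnings.warn(
                f"median split emptied a group for gene {gene!r}; skipped",
                stacklevel=2,
            )
            for pw in pas.index:
                records.append(
                    _record(gene, pw, cancer_type, np.nan, np.nan, np.nan, np.nan)
                )
            continue
        hi, lo = pas_arr[:, high], pas_arr[:, low]
        res = sps.ttest_ind(hi, lo, axis=1, equal_var=True)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        constant = np.ptp(pas_arr, axis=1) == 0
        pvals = np.where(constant, 1.0, pvals)
        for k, pw in enumerate(pas.index):
            records.append(
                _record(
                    gene, pw, cancer_type,
                    hi[k].mean(), lo[k].mean(), float(pvals[k]), np.nan,
                )
            )
    out = pd.DataFrame(records, columns=ASSOCIATION_COLUMNS)
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["verdict"] = [
        _verdict(rec, fdr_threshold) for rec in out.to_dict("records")
    ]
    return out


def pas_global_summary(associations: pd.DataFrame, min_cancers: int = 5) -> pd.DataFrame:
    """Summarize per (gene, pathway) across cancers.

    pct_activated / pct_inhibited are percentages of the cancer types
    tested; ``heatmap_kept`` is True when the gene-pathway pair is
    functional (verdict != none) in at least ``min_cancers`` cancers,
    boundary inclusive.
    """
    if associations.empty:
        raise ValueError("no associations to summarize")
    rows = []
    for (gene, pathway), grp in associations.groupby(["gene", "pathway"], sort=True):
        tested = grp["verdict"].notna().sum()
        n_act = int((grp["verdict"] == "activation").sum())
        n_inh = int((grp["verdict"] == "inhibition").sum())
        functional = n_act + n_inh
        rows.append(
            {
                "gene": gene,
                "pathway": pathway,
                "pct_activated": 100.0 * n_act / tested if tested else np.nan,
                "pct_inhibited": 100.0 * n_inh / tested if tested else np.nan,
                "functional_in": functional,
                "heatmap_kept": functional >= min_cancers,
            }
        )
    return pd.DataFrame(rows)
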