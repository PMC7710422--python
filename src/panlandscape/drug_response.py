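"""Drug-sensitivity analysis across cell lines.

Gene expression is correlated with drug AUC per (gene, drug) pair across
shared cell lines — Spearman by default (the headline statistic), Pearson
as an alternative. Each rho is Fisher-Z transformed (z = atanh(rho)), and
the family-wise error is controlled by a two-tailed Bonferroni test at
family alpha 0.05 (0.025 per tail) over all gene x drug pairs. A positive
rho means higher expression, higher AUC, i.e. resistance; negative means
sensitivity. The planted-pair set is compared against a resampling null:
the mean |rho| of the target pairs versus the same statistic on randomly
sampled non-target pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneSampleMatrix
from .stats import spearman_matrix, _spearman_p_from_rho

__all__ = [
    "correlate_drug_expression",
    "resampling_null",
    "drugs_per_gene",
    "ResamplingComparison",
]

ASSOC_COLUMNS = [
    "gene", "drug", "rho", "z", "p_value", "n",
    "bonferroni_significant", "direction",
]

_RHO_CLIP = 1.0 - 1e-12


def correlate_drug_expression(
    expression: GeneSampleMatrix,
    auc: GeneSampleMatrix,
    method: str = "spearman",
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """All (gene, drug) expression-AUC correlations across shared lines.

    Missing AUC values are allowed and handled pairwise-complete. The
    Bonferroni flag tests p < family_alpha / (n_genes * n_drugs); pairs
    with < 3 complete observations come back as missing-result rows.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = expression.values.columns.intersection(auc.values.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared cell lines, have {len(shared)}")
    expr = expression.values.loc[:, shared]
    auc_v = auc.values.loc[:, shared]
    if method == "spearman":
        rho, p, n = spearman_matrix(expr, auc_v)
    else:
        rho, p, n = _pearson_matrix(expr, auc_v)
    n_tests = len(expr.index) * len(auc_v.index)
    threshold = family_alpha / n_tests
    rows = []
    for gene in expr.index:
        for drug in auc_v.index:
            r = rho.loc[gene, drug]
            z = float(np.arctanh(np.clip(r, -_RHO_CLIP, _RHO_CLIP)))
            pv = p.loc[gene, drug]
            rows.append(
                {
                    "gene": gene,
                    "drug": drug,
                    "rho": r,
                    "z": z if not np.isnan(r) else np.nan,
                    "p_value": pv,
                    "n": int(n.loc[gene, drug]),
                    "bonferroni_significant": bool(pv < threshold)
                    if not np.isnan(pv)
                    else False,
                    "direction": "resistance" if r > 0 else "sensitivity",
                }
            )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def _pearson_matrix(expr: pd.DataFrame, auc: pd.DataFrame):
    """All-pairs Pearson with pairwise-complete handling, p via t-approx
    (same formula as the Spearman path, exact for Pearson under normality)."""
    e = expr.to_numpy(dtype=float)
    a = auc.to_numpy(dtype=float)
    nL, nR = len(e), len(a)
    rho = np.full((nL, nR), np.nan)
    nobs = np.zeros((nL, nR))
    for i in range(nL):
        for j in range(nR):
            ok = ~(np.isnan(e[i]) | np.isnan(a[j]))
            if ok.sum() < 3:
                nobs[i, j] = ok.sum()
                continue
            x, y = e[i, ok], a[j, ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                nobs[i, j] = ok.sum()
                continue
            rho[i, j] = np.corrcoef(x, y)[0, 1]
            nobs[i, j] = ok.sum()
    p = _spearman_p_from_rho(rho, nobs)
    return (
        pd.DataFrame(rho, index=expr.index, columns=auc.index),
        pd.DataFrame(p, index=expr.index, columns=auc.index),
        pd.DataFrame(nobs, index=expr.index, columns=auc.index),
    )


@dataclass
class ResamplingComparison:
    """Observed target-pair statistic versus a random-pair null.

    ``observed_stat`` is the mean |rho| over the target (gene, drug) pairs;
    each null iteration draws the same number of non-target pairs without
    replacement. ``empirical_p = (1 + #{null >= observed}) / (1 + n_iterations)``.
    """

    target_pairs: list[tuple[str, str]]
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    n_iterations: int
    seed: int

    summary: dict = field(init=False)

    def __post_init__(self) -> None:
        self.summary = {
            "observed_mean_abs_rho": self.observed_stat,
            "null_mean": float(np.mean(self.null_stats)),
            "empirical_p": self.empirical_p,
            "n_iterations": self.n_iterations,
        }


def resampling_null(
    associations: pd.DataFrame,
    target_pairs: list[tuple[str, str]],
    n_iterations: int = 1000,
    seed: int = 0,
) -> ResamplingComparison:
    """Compare target-pair correlation strength with random pair sets."""
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if not target_pairs:
        raise ValueError("target_pairs must be non-empty")
    indexed = associations.set_index(["gene", "drug"])["rho"]
    missing = [p for p in target_pairs if p not in indexed.index]
    if missing:
        raise ValueError(f"target pair(s) not in associations: {missing}")
    target_rho = indexed.loc[target_pairs].to_numpy(dtype=float)
    observed = float(np.nanmean(np.abs(target_rho)))
    pool = indexed.drop(index=target_pairs).to_numpy(dtype=float)
    k = len(target_pairs)
    if len(pool) < k:
        raise ValueError(
            f"only {len(pool)} non-target pairs available, need >= {k}"
        )
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_iterations)
    abs_pool = np.abs(pool)
    for it in range(n_iterations):
        idx = rng.choice(len(pool), size=k, replace=False)
        null_stats[it] = np.nanmean(abs_pool[idx])
    empirical_p = (1 + int((null_stats >= observed).sum())) / (1 + n_iterations)
    return ResamplingComparison(
        target_pairs=list(target_pairs),
        observed_stat=observed,
        null_stats=null_stats,
        empirical_p=empirical_p,
        n_iterations=n_iterations,
        seed=seed,
    )


def drugs_per_gene(associations: pd.DataFrame) -> pd.DataFrame:
    """Count of Bonferroni-significant drugs per gene, with the drug list
    sorted by |rho| descending."""
    rows = []
    for gene, grp in associations.groupby("gene", sort=True):
        sig = grp[grp["bonferroni_significant"]].copy()
        sig = sig.reindex(sig["rho"].abs().sort_values(ascending=False).index)
        rows.append(
            {
                "gene": gene,
                "n_significant_drugs": len(sig),
                "drugs": ",".join(sig["drug"].tolist()),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_significant_drugs", "drugs"])
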