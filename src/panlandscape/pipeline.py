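"""End-to-end orchestration of the landscape stages and truth scoring.

``run_all`` executes every analysis stage over a cohort bundle (synthetic
or loaded from disk) and collects the per-stage tables into a
:class:`LandscapeReport` that serializes losslessly to a directory of TSVs
plus a metadata JSON. ``score_against_truth`` compares a report with the
planted-effect registry of the synthetic generator and reports, per stage,
sensitivity (planted effects recovered with the correct sign), the
false-discovery proportion among significant calls, and sign accuracy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import match_tumor_normal, GeneSampleMatrix
from .diffexpr import differential_expression, size_factors
from .cnv_landscape import event_percentages, cnv_expression_correlation
from .methylation_landscape import (
    differential_methylation,
    methylation_expression_correlation,
)
from .mutation_landscape import mutation_frequency, per_sample_summary, combine_maf
from .pathway_activity import pas_associations, pas_global_summary
from .drug_response import correlate_drug_expression, drugs_per_gene, resampling_null
from .survival_landscape import survival_associations
from .synthetic import CohortBundle, SyntheticTruth

__all__ = ["Thresholds", "LandscapeReport", "run_all", "score_against_truth"]

STAGES = ("de", "cnv", "methylation", "mutation", "pas", "drug", "survival")

#: tables each stage contributes to the report
STAGE_TABLES = {
    "de": ["differential_expression"],
    "cnv": ["cnv_profile", "cnv_correlation"],
    "methylation": ["methylation_diff", "methylation_correlation"],
    "mutation": ["mutation_frequency", "mutation_per_sample"],
    "pas": ["pas_association", "pas_summary"],
    "drug": ["drug_association", "drug_counts"],
    "survival": ["survival"],
}


@dataclass
class Thresholds:
    """Every printed analysis threshold, as configuration.

    fold_change / fdr gate the DE calls; cnv_display_pct is the strict
    display rule; pas_min_cancers the inclusive heatmap filter;
    bonferroni_alpha the drug family-wise alpha; survival_alpha the
    per-gene log-rank alpha.
    """

    fold_change: float = 2.0
    fdr: float = 0.05
    cnv_display_pct: float = 5.0
    pas_min_cancers: int = 5
    bonferroni_alpha: float = 0.05
    resampling_iterations: int = 1000
    survival_alpha: float = 0.05
    include_silent: bool = False
    drug_method: str = "spearman"


@dataclass
class LandscapeReport:
    """Per-stage result tables plus run metadata."""

    tables: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in sorted(self.tables.items()):
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=1, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "LandscapeReport":
        path = Path(in_dir)
        tables = {
            # round_trip parsing keeps serialize -> parse -> serialize
            # byte-identical (the default C parser can be 1 ulp off)
            f.stem: pd.read_csv(f, sep="\t", float_precision="round_trip")
            for f in sorted(path.glob("*.tsv"))
        }
        meta_file = path / "metadata.json"
        metadata = json.loads(meta_file.read_text()) if meta_file.exists() else {}
        return cls(tables=tables, metadata=metadata)


def _normalized_log_expression(counts: GeneSampleMatrix) -> GeneSampleMatrix:
    factors = size_factors(counts)
    norm = np.log2(counts.values.div(factors, axis=1) + 1.0)
    return GeneSampleMatrix(norm, "normalized_expression")


def run_all(
    bundle: CohortBundle,
    thresholds: Thresholds | None = None,
    stages: tuple[str, ...] = STAGES,
    target_pairs: list[tuple[str, str]] | None = None,
) -> LandscapeReport:
    """Run the enabled stages over a cohort bundle, in dependency order.

    Preflight checks that every enabled stage's inputs exist in the bundle
    before any stage runs (fail fast). ``target_pairs`` enables the
    drug-stage resampling comparison.
    """
    th = thresholds or Thresholds()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    if not stages:
        raise ValueError("at least one stage must be enabled")
    _preflight(bundle, stages)

    cancers = list(bundle.config.cancer_types)
    # PAS, drug and survival associations are computed for the configured
    # target gene family (the landscape's subjects); DE, CNV and
    # methylation run genome-wide over whatever the matrices carry.
    target_genes = list(bundle.config.target_genes)
    log_expr = {c: _normalized_log_expression(bundle.counts[c]) for c in cancers}
    tables: dict[str, pd.DataFrame] = {}

    if "de" in stages:
        parts = []
        for c in cancers:
            split = match_tumor_normal(bundle.counts[c])
            parts.append(
                differential_expression(
                    bundle.counts[c], split.tumors, split.normals, c,
                    fc_threshold=th.fold_change, fdr_threshold=th.fdr,
                )
            )
        tables["differential_expression"] = pd.concat(parts, ignore_index=True)

    if "cnv" in stages:
        profiles, corrs = [], []
        for c in cancers:
            profiles.append(
                event_percentages(bundle.cnv[c], c, display_threshold_pct=th.cnv_display_pct)
            )
            corrs.append(cnv_expression_correlation(bundle.cnv[c], log_expr[c], c))
        tables["cnv_profile"] = pd.concat(profiles, ignore_index=True)
        tables["cnv_correlation"] = pd.concat(corrs, ignore_index=True)

    if "methylation" in stages:
        diffs, corrs = [], []
        for c in cancers:
            split = match_tumor_normal(bundle.beta[c])
            diffs.append(
                differential_methylation(
                    bundle.beta[c], split.tumors, split.normals, c, fdr_threshold=th.fdr
                )
            )
            corrs.append(
                methylation_expression_correlation(bundle.beta[c], log_expr[c], c)
            )
        tables["methylation_diff"] = pd.concat(diffs, ignore_index=True)
        tables["methylation_correlation"] = pd.concat(corrs, ignore_index=True)

    if "mutation" in stages:
        genes = list(bundle.config.all_genes)
        freqs = [
            mutation_frequency(bundle.maf[c], genes, c, include_silent=th.include_silent)
            for c in cancers
        ]
        pan = combine_maf(bundle.maf)
        freqs.append(
            mutation_frequency(pan, genes, "pan-cancer", include_silent=th.include_silent)
        )
        tables["mutation_frequency"] = pd.concat(freqs, ignore_index=True)
        tables["mutation_per_sample"] = per_sample_summary(pan).reset_index()

    if "pas" in stages:
        parts = [
            pas_associations(
                log_expr[c].subset_samples(bundle.rppa[c].samples),
                bundle.rppa[c],
                bundle.pathways,
                c,
                genes=target_genes,
                fdr_threshold=th.fdr,
            )
            for c in cancers
        ]
        assoc = pd.concat(parts, ignore_index=True)
        tables["pas_association"] = assoc
        tables["pas_summary"] = pas_global_summary(assoc, min_cancers=th.pas_min_cancers)

    if "drug" in stages:
        cellline_targets = [
            g for g in target_genes if g in bundle.cellline_expression.values.index
        ]
        assoc = correlate_drug_expression(
            bundle.cellline_expression.subset_genes(cellline_targets),
            bundle.drug_auc,
            method=th.drug_method,
            family_alpha=th.bonferroni_alpha,
        )
        tables["drug_association"] = assoc
        tables["drug_counts"] = drugs_per_gene(assoc)
        if target_pairs:
            cmp = resampling_null(
                assoc, target_pairs,
                n_iterations=th.resampling_iterations,
                seed=bundle.config.seed,
            )
            tables["drug_resampling"] = pd.DataFrame([cmp.summary])

    if "survival" in stages:
        parts = [
            survival_associations(
                log_expr[c].subset_samples(
                    [s for s in bundle.survival[c]["sample"]]
                ),
                bundle.survival[c],
                genes=target_genes,
                cancer_type=c,
                alpha=th.survival_alpha,
            )
            for c in cancers
        ]
        tables["survival"] = pd.concat(parts, ignore_index=True)

    metadata = {
        "seed": bundle.config.seed,
        "stages": list(stages),
        "thresholds": asdict(th),
        "config_hash": hashlib.sha256(
            repr(bundle.config).encode()
        ).hexdigest()[:16],
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return LandscapeReport(tables=tables, metadata=metadata)


def _preflight(bundle: CohortBundle, stages) -> None:
    cancers = bundle.config.cancer_types
    needs = {
        "de": [bundle.counts],
        "cnv": [bundle.cnv, bundle.counts],
        "methylation": [bundle.beta, bundle.counts],
        "mutation": [bundle.maf],
        "pas": [bundle.rppa, bundle.counts],
        "survival": [bundle.survival, bundle.counts],
    }
    for stage in stages:
        for layer in needs.get(stage, []):
            missing = [c for c in cancers if c not in layer]
            if missing:
                raise ValueError(
                    f"stage {stage!r} enabled but layer missing for cancer(s) {missing}"
                )
    if "drug" in stages and (
        bundle.cellline_expression is None or bundle.drug_auc is None
    ):
        raise ValueError("stage 'drug' enabled but cell-line layers are missing")


def _score(planted: dict, calls: dict) -> dict:
    """planted: key -> expected sign; calls: key -> observed sign or None."""
    n_planted = len(planted)
    called_planted = {k: s for k, s in calls.items() if k in planted and s is not None}
    recovered = sum(1 for k, s in called_planted.items() if s == planted[k])
    n_calls = sum(1 for s in calls.values() if s is not None)
    false_calls = sum(
        1 for k, s in calls.items() if s is not None and k not in planted
    )
    return {
        "sensitivity": recovered / n_planted if n_planted else np.nan,
        "false_discovery": false_calls / n_calls if n_calls else 0.0,
        "sign_accuracy": (
            sum(1 for k, s in called_planted.items() if s == planted[k])
            / len(called_planted)
            if called_planted
            else np.nan
        ),
    }


def score_against_truth(
    report: LandscapeReport,
    truth: SyntheticTruth,
    fdr_threshold: float = 0.05,
    mutation_tolerance_pct: float = 7.0,
) -> pd.DataFrame:
    """Per-stage recovery scores against the planted-effect registry."""
    if not report.tables:
        raise ValueError("empty report")
    rows = []

    def stage_row(stage, planted, calls):
        rows.append({"stage": stage, **_score(planted, calls)})

    if "differential_expression" in report.tables:
        de = report.tables["differential_expression"]
        _check_universe(de["gene"], truth.de_log2fc)
        planted = {k: np.sign(v) for k, v in truth.de_log2fc.items() if v != 0}
        calls = {
            (r.gene, r.cancer_type): (1.0 if r.status == "up" else -1.0)
            if r.status != "ns"
            else None
            for r in de.itertuples()
        }
        stage_row("de", planted, calls)

    if "cnv_correlation" in report.tables:
        cc = report.tables["cnv_correlation"]
        planted = {}
        for g, slope in truth.cnv_dosage_slope.items():
            if slope != 0:
                for c in cc["cancer_type"].unique():
                    planted[(g, c)] = np.sign(slope)
        calls = {
            (r.gene, r.cancer_type): np.sign(r.rho)
            if not np.isnan(r.fdr) and r.fdr < fdr_threshold
            else None
            for r in cc.itertuples()
        }
        stage_row("cnv_correlation", planted, calls)

    if "methylation_diff" in report.tables:
        md = report.tables["methylation_diff"]
        planted = {k: np.sign(v) for k, v in truth.meth_effect.items() if v != 0}
        calls = {
            (r.gene, r.cancer_type): (1.0 if r.direction == "hyper" else -1.0)
            if r.direction != "ns"
            else None
            for r in md.itertuples()
        }
        stage_row("methylation_diff", planted, calls)

    if "methylation_correlation" in report.tables:
        mc = report.tables["methylation_correlation"]
        planted = {}
        for g, slope in truth.meth_expr_slope.items():
            if slope != 0:
                for c in mc["cancer_type"].unique():
                    planted[(g, c)] = np.sign(slope)
        calls = {
            (r.gene, r.cancer_type): np.sign(r.rho)
            if not np.isnan(r.fdr) and r.fdr < fdr_threshold
            else None
            for r in mc.itertuples()
        }
        stage_row("methylation_correlation", planted, calls)

    if "mutation_frequency" in report.tables:
        mf = report.tables["mutation_frequency"]
        per_cancer = mf[mf["cancer_type"] != "pan-cancer"]
        planted_freq = {k: 100.0 * v for k, v in truth.mut_freq.items() if v > 0}
        n_recovered = 0
        false_pos = 0
        n_pos_calls = 0
        for r in per_cancer.itertuples():
            key = (r.gene, r.cancer_type)
            if key in planted_freq:
                if abs(r.frequency_pct - planted_freq[key]) <= mutation_tolerance_pct:
                    n_recovered += 1
                n_pos_calls += 1
            elif r.frequency_pct > 0:
                false_pos += 1
                n_pos_calls += 1
        rows.append(
            {
                "stage": "mutation_frequency",
                "sensitivity": n_recovered / len(planted_freq) if planted_freq else np.nan,
                "false_discovery": false_pos / n_pos_calls if n_pos_calls else 0.0,
                "sign_accuracy": np.nan,
            }
        )

    if "pas_association" in report.tables:
        pa = report.tables["pas_association"]
        planted = {k: np.sign(v) for k, v in truth.pas_shift.items() if v != 0}
        calls = {
            (r.gene, r.pathway, r.cancer_type): (
                1.0 if r.verdict == "activation" else -1.0
            )
            if r.verdict in ("activation", "inhibition")
            else None
            for r in pa.itertuples()
        }
        stage_row("pas", planted, calls)

    if "drug_association" in report.tables:
        da = report.tables["drug_association"]
        planted = {k: np.sign(v) for k, v in truth.drug_rho.items() if v != 0}
        calls = {
            (r.gene, r.drug): np.sign(r.rho) if r.bonferroni_significant else None
            for r in da.itertuples()
        }
        stage_row("drug", planted, calls)

    if "survival" in report.tables:
        sv = report.tables["survival"]
        sign_of = {"unfavorable": 1.0, "favorable": -1.0}
        planted = {
            k: sign_of[d]
            for k, d in truth.hazard_direction.items()
            if d != "none"
        }
        calls = {
            (r.gene, r.cancer_type): sign_of.get(r.verdict)
            for r in sv.itertuples()
        }
        stage_row("survival", planted, calls)

    return pd.DataFrame(rows, columns=["stage", "sensitivity", "false_discovery", "sign_accuracy"])


def _check_universe(report_genes: pd.Series, planted: dict) -> None:
    universe = set(report_genes)
    stray = {g for g, *_ in planted} - universe
    if stray:
        raise ValueError(f"truth references gene(s) absent from report: {sorted(stray)}")
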