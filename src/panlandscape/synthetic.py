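"""Synthetic multi-cancer, multi-omic cohort with planted, recorded effects.

The generator emulates the data universe the landscape pipeline consumes —
tumor/normal RNA counts, gene-level CNV calls, promoter-methylation betas,
a somatic MAF, RPPA protein levels, cell-line drug AUCs and right-censored
survival — while recording every planted effect in a
:class:`SyntheticTruth` registry so each stage can be scored for recovery.

A single latent expression value per sample links the layers: CNV dosage
and the methylation residual both feed the negative-binomial mean, the
realized counts define the high/low groups that shift RPPA levels and
survival hazards, and cell-line AUCs are tied to expression through a
Gaussian copula. Cross-layer correlations in the output are therefore
real, not coincidental.

Default planted effects mirror the qualitative pan-cancer claims the
pipeline is meant to surface (HIF3A/EPAS1 down, positive CNV dosage
slopes, methylation anticorrelated with expression, mutation frequencies
of 17-31%, EMT activation, EPAS1 drug correlations including docetaxel,
and gene-specific favorable/unfavorable survival directions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import GeneSampleMatrix, MafTable, read_maf, read_matrix, write_matrix, write_maf
from .pathway_activity import PathwayDefinition

__all__ = [
    "TARGET_GENES",
    "CANCER_TYPES",
    "CohortConfig",
    "SyntheticTruth",
    "CohortBundle",
    "default_truth",
    "emit_pathway_definitions",
    "generate_cohort",
    "load_bundle",
]

TARGET_GENES = ("HIF1A", "ARNT", "EPAS1", "ARNT2", "HIF3A", "ARNTL")

CANCER_TYPES = (
    "THCA", "KIRP", "LIHC", "STAD", "BRCA", "COAD",
    "UCEC", "BLCA", "KIRC", "KICH", "PRAD",
)

PATHWAY_NAMES = (
    "apoptosis",
    "cell cycle",
    "DNA damage response",
    "EMT",
    "hormone AR",
    "hormone ER",
    "PI3K/AKT",
    "RAS/MAPK",
    "RTK",
    "TSC/mTOR",
)

#: variant classes drawn for a planted non-silent mutation (7:1:1)
_NONSILENT_CLASSES = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del")
_NONSILENT_P = (7 / 9, 1 / 9, 1 / 9)

_SNV_PAIRS = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a and (r, a) not in {("C", "G"), ("G", "C")}
]

_HR_BY_DIRECTION = {"unfavorable": 2.0, "favorable": 0.5, "none": 1.0}


def emit_pathway_definitions() -> list[PathwayDefinition]:
    """The ten hallmark pathways with synthetic signed member components.

    Member IDs are synthetic antibody-style labels, not real RPPA antibody
    names; signs mark activating (+1) vs inhibitory (-1) components, with
    inhibitory members present in several pathways to exercise sign
    handling.
    """
    spec = {
        "apoptosis": [("APO_caspase_a", 1), ("APO_caspase_b", 1), ("APO_blocker", -1)],
        "cell cycle": [("CC_cyclin_a", 1), ("CC_cyclin_b", 1), ("CC_kinase", 1), ("CC_brake", -1)],
        "DNA damage response": [("DDR_sensor", 1), ("DDR_kinase", 1), ("DDR_effector", 1)],
        "EMT": [("EMT_mesenchymal_a", 1), ("EMT_mesenchymal_b", 1), ("EMT_epithelial", -1)],
        "hormone AR": [("AR_receptor", 1), ("AR_coact", 1), ("AR_corepressor", -1)],
        "hormone ER": [("ER_receptor", 1), ("ER_coact_a", 1), ("ER_coact_b", 1)],
        "PI3K/AKT": [("PI3K_kinase", 1), ("PI3K_akt", 1), ("PI3K_pten", -1)],
        "RAS/MAPK": [("RAS_gtpase", 1), ("RAS_mek", 1), ("RAS_erk", 1)],
        "RTK": [("RTK_egfr", 1), ("RTK_her2", 1), ("RTK_met", 1)],
        "TSC/mTOR": [("MTOR_kinase", 1), ("MTOR_s6k", 1), ("MTOR_tsc", -1)],
    }
    return [PathwayDefinition(name, tuple(spec[name])) for name in PATHWAY_NAMES]


@dataclass
class SyntheticTruth:
    """Registry of every planted effect, keyed by gene / cancer / pathway / drug.

    Absent keys mean a zero (null) effect. ``hazard_direction`` values are
    'favorable', 'unfavorable' or 'none'.
    """

    de_log2fc: dict = field(default_factory=dict)          # (gene, cancer) -> log2 FC
    cnv_dosage_slope: dict = field(default_factory=dict)   # gene -> slope
    meth_effect: dict = field(default_factory=dict)        # (gene, cancer) -> beta shift
    meth_expr_slope: dict = field(default_factory=dict)    # gene -> log2-expr per logit-beta
    mut_freq: dict = field(default_factory=dict)           # (gene, cancer) -> probability
    pas_shift: dict = field(default_factory=dict)          # (gene, pathway, cancer) -> PAS shift
    drug_rho: dict = field(default_factory=dict)           # (gene, drug) -> correlation
    hazard_direction: dict = field(default_factory=dict)   # (gene, cancer) -> direction

    def __post_init__(self) -> None:
        for name in (
            "de_log2fc", "cnv_dosage_slope", "meth_effect",
            "meth_expr_slope", "mut_freq", "pas_shift",
        ):
            for key, v in getattr(self, name).items():
                if not math.isfinite(v):
                    raise ValueError(f"{name}[{key!r}] is not finite")
        for key, rho in self.drug_rho.items():
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"drug_rho[{key!r}] = {rho} outside (-1, 1)")
        for key, d in self.hazard_direction.items():
            if d not in _HR_BY_DIRECTION:
                raise ValueError(f"hazard_direction[{key!r}] = {d!r} invalid")

    def to_json(self, path: str | Path) -> None:
        def nest(d: Mapping) -> dict:
            out: dict = {}
            for key, v in d.items():
                parts = key if isinstance(key, tuple) else (key,)
                cur = out
                for p in parts[:-1]:
                    cur = cur.setdefault(p, {})
                cur[parts[-1]] = v
            return out

        payload = {name: nest(val) for name, val in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())

        def flatten(d: dict, depth: int) -> dict:
            if depth == 1:
                return dict(d)
            out = {}
            for k, v in d.items():
                for sub, val in flatten(v, depth - 1).items():
                    sub = sub if isinstance(sub, tuple) else (sub,)
                    out[(k, *sub)] = val
            return out

        depths = {
            "de_log2fc": 2, "cnv_dosage_slope": 1, "meth_effect": 2,
            "meth_expr_slope": 1, "mut_freq": 2, "pas_shift": 3,
            "drug_rho": 2, "hazard_direction": 2,
        }
        return cls(**{name: flatten(payload.get(name, {}), d) for name, d in depths.items()})


def default_truth(
    cancer_types: tuple[str, ...] = CANCER_TYPES,
    drug_names: tuple[str, ...] = (),
) -> SyntheticTruth:
    """The default planted-effect registry (the study conditions)."""
    de = {}
    for c in cancer_types:
        de[("HIF3A", c)] = -2.0
        de[("EPAS1", c)] = -2.0
        de[("HIF1A", c)] = -1.5
        de[("ARNT", c)] = 1.5
    meth = {}
    for c in cancer_types:
        meth[("ARNT", c)] = -0.2       # hypomethylated where upregulated
        for g in ("HIF1A", "EPAS1", "HIF3A"):
            meth[(g, c)] = 0.2
    base_freq = {
        "HIF1A": 0.20, "ARNT": 0.20, "EPAS1": 0.26,
        "ARNT2": 0.20, "HIF3A": 0.26, "ARNTL": 0.17,
    }
    mut = {(g, c): f for g, f in base_freq.items() for c in cancer_types}
    if "UCEC" in cancer_types:
        mut[("EPAS1", "UCEC")] = 0.31
    pas = {}
    for c in cancer_types:
        for g in TARGET_GENES:
            pas[(g, "EMT", c)] = 1.0
            pas[(g, "cell cycle", c)] = -1.0
            pas[(g, "DNA damage response", c)] = -1.0
        pas[("HIF3A", "PI3K/AKT", c)] = 1.0
    drug_rho = {}
    if drug_names:
        planted = [
            ("Docetaxel", -0.6), ("DRUG02", -0.5), ("DRUG03", 0.5),
            ("DRUG04", -0.45), ("DRUG05", 0.45),
        ]
        for drug, rho in planted:
            if drug in drug_names:
                drug_rho[("EPAS1", drug)] = rho
    hazard = {}
    for c in cancer_types:
        for g in ("HIF1A", "ARNT", "EPAS1", "HIF3A"):
            hazard[(g, c)] = "unfavorable"
        for g in ("ARNTL", "ARNT2"):
            hazard[(g, c)] = "favorable"
    return SyntheticTruth(
        de_log2fc=de,
        cnv_dosage_slope={g: 0.5 for g in TARGET_GENES},
        meth_effect=meth,
        meth_expr_slope={g: -0.8 for g in TARGET_GENES},
        mut_freq=mut,
        pas_shift=pas,
        drug_rho=drug_rho,
        hazard_direction=hazard,
    )


def _default_drug_names(n_drugs: int) -> tuple[str, ...]:
    names = ["Docetaxel"] + [f"DRUG{i:02d}" for i in range(2, n_drugs + 1)]
    return tuple(names[:n_drugs])


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``truth=None`` selects the default planted-effect registry; pass an
    explicit :class:`SyntheticTruth` (e.g. an empty one) for calibration
    and recovery experiments.
    """

    cancer_types: tuple[str, ...] = CANCER_TYPES
    target_genes: tuple[str, ...] = TARGET_GENES
    n_background_genes: int = 200
    n_tumor: int = 40
    n_normal: int = 20
    n_cell_lines: int = 120
    n_drugs: int = 30
    seed: int = 0
    nb_dispersion: float = 0.1
    beta_logit_sd: float = 0.5
    cnv_event_rates: tuple[float, ...] = (0.05, 0.15, 0.60, 0.15, 0.05)
    censoring_fraction: float = 0.30
    base_hazard: float = 1.0 / 1000.0  # events per day
    snv_cg_enrichment: float = 0.5     # fraction of SNVs forced to the C>G class
    drug_names: tuple[str, ...] | None = None
    truth: SyntheticTruth | None = None

    def __post_init__(self) -> None:
        if self.n_tumor < 3 or self.n_normal < 3:
            raise ValueError("n_tumor and n_normal must be >= 3")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.cnv_event_rates) != 5 or not math.isclose(
            sum(self.cnv_event_rates), 1.0, abs_tol=1e-9
        ):
            raise ValueError("cnv_event_rates must be 5 probabilities summing to 1")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        if not (0 <= self.snv_cg_enrichment <= 1):
            raise ValueError("snv_cg_enrichment must be in [0, 1]")
        self.cancer_types = tuple(self.cancer_types)
        self.target_genes = tuple(self.target_genes)
        if self.drug_names is None:
            self.drug_names = _default_drug_names(self.n_drugs)
        self.drug_names = tuple(self.drug_names)
        if len(self.drug_names) != self.n_drugs:
            raise ValueError("drug_names length must equal n_drugs")
        if self.truth is None:
            self.truth = default_truth(self.cancer_types, self.drug_names)
        self._validate_truth()

    def _validate_truth(self) -> None:
        genes = set(self.all_genes)
        t = self.truth
        planted_genes = (
            {g for g, _ in t.de_log2fc}
            | set(t.cnv_dosage_slope)
            | {g for g, _ in t.meth_effect}
            | set(t.meth_expr_slope)
            | {g for g, _ in t.mut_freq}
            | {g for g, _, _ in t.pas_shift}
            | {g for g, _ in t.drug_rho}
            | {g for g, _ in t.hazard_direction}
        )
        stray = planted_genes - genes
        if stray:
            raise ValueError(f"planted effects reference unknown gene(s): {sorted(stray)}")

    @property
    def background_genes(self) -> tuple[str, ...]:
        return tuple(f"BG{i:04d}" for i in range(1, self.n_background_genes + 1))

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.target_genes + self.background_genes


@dataclass
class CohortBundle:
    """Everything one synthetic run produces, one matrix per layer per cancer."""

    config: CohortConfig
    truth: SyntheticTruth
    pathways: list[PathwayDefinition]
    counts: dict[str, GeneSampleMatrix]
    cnv: dict[str, GeneSampleMatrix]
    beta: dict[str, GeneSampleMatrix]
    rppa: dict[str, GeneSampleMatrix]
    maf: dict[str, MafTable]
    survival: dict[str, pd.DataFrame]
    cellline_expression: GeneSampleMatrix
    drug_auc: GeneSampleMatrix

    def save(self, out_dir: str | Path) -> None:
        """Write one TSV per layer per cancer plus the truth registry."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cancer in self.config.cancer_types:
            write_matrix(self.counts[cancer], out / f"{cancer}.counts.tsv")
            write_matrix(self.cnv[cancer], out / f"{cancer}.cnv.tsv")
            write_matrix(self.beta[cancer], out / f"{cancer}.beta.tsv")
            write_matrix(self.rppa[cancer], out / f"{cancer}.rppa.tsv")
            write_maf(self.maf[cancer], out / f"{cancer}.maf.tsv")
            self.survival[cancer].to_csv(
                out / f"{cancer}.survival.tsv", sep="\t", index=False
            )
        write_matrix(self.cellline_expression, out / "celllines.expression.tsv")
        write_matrix(self.drug_auc, out / "celllines.auc.tsv")
        pw = pd.DataFrame(
            [
                {"pathway": p.name, "component": m, "sign": s}
                for p in self.pathways
                for m, s in p.members
            ]
        )
        pw.to_csv(out / "pathways.tsv", sep="\t", index=False)
        self.truth.to_json(out / "truth.json")


def load_bundle(in_dir: str | Path, seed: int = 0) -> CohortBundle:
    """Load a cohort bundle previously written by :meth:`CohortBundle.save`.

    Cancer types are inferred from the ``<CANCER>.counts.tsv`` file names.
    The reconstructed config describes the on-disk data (gene list, drugs,
    cancer types); per-group sample counts and generator noise parameters
    are not recoverable from the files and keep their defaults.
    """
    path = Path(in_dir)
    cancers = sorted(p.name.split(".")[0] for p in path.glob("*.counts.tsv"))
    if not cancers:
        raise FileNotFoundError(f"no '<CANCER>.counts.tsv' files found in {path}")
    counts, cnv, beta, rppa, maf, surv = {}, {}, {}, {}, {}, {}
    for c in cancers:
        counts[c] = read_matrix(path / f"{c}.counts.tsv", "raw_count")
        cnv[c] = read_matrix(path / f"{c}.cnv.tsv", "cnv_call")
        beta[c] = read_matrix(path / f"{c}.beta.tsv", "beta")
        rppa[c] = read_matrix(path / f"{c}.rppa.tsv", "protein_level")
        tumor_samples = cnv[c].samples
        maf[c] = read_maf(path / f"{c}.maf.tsv", tumor_samples)
        surv[c] = pd.read_csv(path / f"{c}.survival.tsv", sep="\t")
    cellline_expr = read_matrix(path / "celllines.expression.tsv", "normalized_expression")
    auc = read_matrix(path / "celllines.auc.tsv", "drug_auc")
    pw_table = pd.read_csv(path / "pathways.tsv", sep="\t")
    pathways = [
        PathwayDefinition(name, tuple(zip(grp["component"], grp["sign"].astype(int))))
        for name, grp in pw_table.groupby("pathway", sort=False)
    ]
    truth_file = path / "truth.json"
    truth = SyntheticTruth.from_json(truth_file) if truth_file.exists() else SyntheticTruth()
    genes = tuple(counts[cancers[0]].genes)
    config = CohortConfig(
        cancer_types=tuple(cancers),
        target_genes=genes,
        n_background_genes=0,
        n_cell_lines=len(auc.samples),
        n_drugs=len(auc.genes),
        drug_names=tuple(auc.genes),
        seed=seed,
        truth=truth,
    )
    return CohortBundle(
        config=config, truth=truth, pathways=pathways,
        counts=counts, cnv=cnv, beta=beta, rppa=rppa, maf=maf,
        survival=surv, cellline_expression=cellline_expr, drug_auc=auc,
    )


def _barcodes(cancer: str, n_tumor: int, n_normal: int) -> tuple[list[str], list[str]]:
    tumors = [f"SYN-{cancer}-{i:04d}-01A" for i in range(n_tumor)]
    normals = [f"SYN-{cancer}-{i:04d}-11A" for i in range(n_normal)]
    return tumors, normals


def _median_high(values: np.ndarray) -> np.ndarray:
    """Median split with ties going low, matching the analysis stages."""
    return values > np.median(values)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full cohort bundle; same config + seed is bit-reproducible."""
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    genes = list(config.all_genes)
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    pathways = emit_pathway_definitions()
    components = [m for p in pathways for m, _ in p.members]

    counts_by, cnv_by, beta_by, rppa_by = {}, {}, {}, {}
    maf_by, surv_by = {}, {}

    for cancer in config.cancer_types:
        tumors, normals = _barcodes(cancer, config.n_tumor, config.n_normal)
        samples = tumors + normals
        n_t, n_s = len(tumors), len(samples)
        is_tumor = np.zeros(n_s, dtype=bool)
        is_tumor[:n_t] = True

        base_log2 = rng.uniform(4.0, 12.0, n_genes)          # 2^4 .. 2^12
        base_beta = rng.uniform(0.15, 0.85, n_genes)
        mu_logit = logit(base_beta)

        # CNV calls (tumors only; the portal's gene-level calls cover tumors)
        calls = rng.choice(
            np.array([-2, -1, 0, 1, 2]), size=(n_genes, n_t), p=config.cnv_event_rates
        )

        # methylation: planted tumor-normal beta shift on the logit scale
        delta_logit = np.zeros(n_genes)
        for (g, c), eff in truth.meth_effect.items():
            if c == cancer and g in gene_idx:
                b = base_beta[gene_idx[g]]
                shifted = np.clip(b + eff, 1e-3, 1 - 1e-3)
                delta_logit[gene_idx[g]] = logit(shifted) - logit(b)
        center = mu_logit[:, None] + delta_logit[:, None] * is_tumor[None, :]
        logit_beta = center + rng.normal(0.0, config.beta_logit_sd, (n_genes, n_s))
        beta = expit(logit_beta)

        # expression mean: baseline x planted DE x CNV dosage x methylation residual
        log2_mean = np.tile(base_log2[:, None], (1, n_s))
        for (g, c), lfc in truth.de_log2fc.items():
            if c == cancer and g in gene_idx:
                log2_mean[gene_idx[g], is_tumor] += lfc
        dosage = np.ones((n_genes, n_t))
        for g, slope in truth.cnv_dosage_slope.items():
            if g in gene_idx:
                i = gene_idx[g]
                dosage[i] = np.clip(1.0 + slope * calls[i] / 2.0, 0.05, None)
        log2_mean[:, :n_t] += np.log2(dosage)
        slope_me = np.zeros(n_genes)
        for g, s in truth.meth_expr_slope.items():
            if g in gene_idx:
                slope_me[gene_idx[g]] = s
        log2_mean += slope_me[:, None] * (logit_beta - center)

        mean = np.exp2(log2_mean)
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean * config.nb_dispersion)
        counts = rng.poisson(lam).astype(float)

        counts_by[cancer] = GeneSampleMatrix(
            pd.DataFrame(counts, index=genes, columns=samples), "raw_count"
        )
        cnv_by[cancer] = GeneSampleMatrix(
            pd.DataFrame(calls.astype(float), index=genes, columns=tumors), "cnv_call"
        )
        beta_by[cancer] = GeneSampleMatrix(
            pd.DataFrame(beta, index=genes, columns=samples), "beta"
        )

        maf_by[cancer] = _simulate_maf(rng, config, truth, cancer, genes, tumors)
        rppa_by[cancer] = _simulate_rppa(
            rng, truth, cancer, pathways, components, counts[:, :n_t], gene_idx, tumors
        )
        surv_by[cancer] = _simulate_survival(
            rng, config, truth, cancer, counts[:, :n_t], gene_idx, tumors
        )

    cellline_expr, auc = _simulate_celllines(rng, config, truth, genes)

    return CohortBundle(
        config=config,
        truth=truth,
        pathways=pathways,
        counts=counts_by,
        cnv=cnv_by,
        beta=beta_by,
        rppa=rppa_by,
        maf=maf_by,
        survival=surv_by,
        cellline_expression=cellline_expr,
        drug_auc=auc,
    )


def _simulate_maf(rng, config, truth, cancer, genes, tumors) -> MafTable:
    """Planted per-gene mutation frequencies with a 7:1:1 non-silent class mix.

    The planted frequency is the probability of a non-silent record, so the
    silent-excluding frequency estimator is unbiased for it; an independent
    Silent record is added at a tenth of that rate, approximating a
    70/10/10/10 Missense/Nonsense/Silent/Frame_Shift_Del spectrum.
    """
    rows = []
    n_t = len(tumors)
    for g in genes:
        freq = truth.mut_freq.get((g, cancer), 0.0)
        if freq <= 0:
            continue
        hit = rng.random(n_t) < freq
        classes = rng.choice(_NONSILENT_CLASSES, size=n_t, p=_NONSILENT_P)
        silent_hit = rng.random(n_t) < 0.1 * freq
        for j in range(n_t):
            if hit[j]:
                rows.append(_maf_row(rng, config, g, tumors[j], classes[j]))
            if silent_hit[j]:
                rows.append(_maf_row(rng, config, g, tumors[j], "Silent"))
    records = pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification",
            "Reference_Allele", "Tumor_Seq_Allele2",
        ],
    )
    return MafTable(records=records, cohort_samples=list(tumors))


def _maf_row(rng, config, gene, sample, classification) -> dict:
    if classification == "Frame_Shift_Del":
        ref, alt = rng.choice(list("ACGT")), "-"
    elif rng.random() < config.snv_cg_enrichment:
        ref, alt = ("C", "G") if rng.random() < 0.5 else ("G", "C")
    else:
        ref, alt = _SNV_PAIRS[rng.integers(len(_SNV_PAIRS))]
    return {
        "Hugo_Symbol": gene,
        "Tumor_Sample_Barcode": sample,
        "Variant_Classification": classification,
        "Reference_Allele": ref,
        "Tumor_Seq_Allele2": alt,
    }


def _simulate_rppa(
    rng, truth, cancer, pathways, components, tumor_counts, gene_idx, tumors
) -> GeneSampleMatrix:
    """Member proteins ~ N(0,1); planted shifts move each member by
    sign * pas_shift for expression-high samples, so the realized PAS
    displacement between groups equals the planted value."""
    n_t = len(tumors)
    levels = rng.normal(0.0, 1.0, (len(components), n_t))
    comp_idx = {cmp: i for i, cmp in enumerate(components)}
    members_by_pathway = {p.name: p.members for p in pathways}
    for (g, pw, c), shift in truth.pas_shift.items():
        if c != cancer or g not in gene_idx or pw not in members_by_pathway:
            continue
        high = _median_high(tumor_counts[gene_idx[g]])
        for m, sign in members_by_pathway[pw]:
            levels[comp_idx[m], high] += sign * shift
    return GeneSampleMatrix(
        pd.DataFrame(levels, index=components, columns=tumors), "protein_level"
    )


def _simulate_survival(
    rng, config, truth, cancer, tumor_counts, gene_idx, tumors
) -> pd.DataFrame:
    """Exponential event times; each planted gene multiplies the hazard by
    2 (unfavorable) or 0.5 (favorable) for its expression-high half.
    Independent exponential censoring targets ~30% censored records."""
    n_t = len(tumors)
    rate = np.full(n_t, config.base_hazard)
    for (g, c), direction in truth.hazard_direction.items():
        if c != cancer or g not in gene_idx:
            continue
        hr = _HR_BY_DIRECTION[direction]
        high = _median_high(tumor_counts[gene_idx[g]])
        rate[high] *= hr
    event_time = rng.exponential(1.0 / rate)
    cf = config.censoring_fraction
    if cf > 0:
        c_rate = config.base_hazard * cf / (1.0 - cf)
        censor_time = rng.exponential(1.0 / c_rate, n_t)
    else:
        censor_time = np.full(n_t, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"sample": tumors, "time": time, "event": event})


def _simulate_celllines(rng, config, truth, genes):
    """Gaussian-copula cell-line layer: AUC latent = rho * z_gene +
    sqrt(1 - rho^2) * noise for each planted (gene, drug) pair."""
    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    z = rng.normal(0.0, 1.0, (len(genes), len(lines)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    planted_by_drug: dict[str, tuple[str, float]] = {}
    for (g, d), rho in truth.drug_rho.items():
        if d in planted_by_drug:
            raise ValueError(f"drug {d!r} has more than one planted gene")
        planted_by_drug[d] = (g, rho)
    auc = np.empty((config.n_drugs, len(lines)))
    for k, drug in enumerate(config.drug_names):
        noise = rng.normal(0.0, 1.0, len(lines))
        if drug in planted_by_drug:
            g, rho = planted_by_drug[drug]
            auc[k] = rho * z[gene_idx[g]] + math.sqrt(1.0 - rho**2) * noise
        else:
            auc[k] = noise
    expr = GeneSampleMatrix(
        pd.DataFrame(z, index=genes, columns=lines), "normalized_expression"
    )
    auc_m = GeneSampleMatrix(
        pd.DataFrame(auc, index=list(config.drug_names), columns=lines), "drug_auc"
    )
    return expr, auc_m
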