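"""Somatic-mutation summarization from a MAF.

Re-implements the usual MAF summaries: per-gene mutation frequency (a
sample counts once per gene, Silent records excluded by default), the
variant-classification spectrum, the six-class SNV base-change spectrum
collapsed to pyrimidine context (C>A, C>G, C>T, T>A, T>C, T>G), the
per-sample burden table, and a gene x sample oncoplot matrix. The
frequency denominator is the full cohort sample universe, so unmutated
samples dilute the percentage.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .io_formats import MafTable, MAF_CLASSIFICATIONS

__all__ = [
    "SNV_CLASSES",
    "snv_class",
    "mutation_frequency",
    "per_sample_summary",
    "oncoplot_matrix",
    "combine_maf",
]

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: purine-reference substitutions collapsed onto their pyrimidine complement
_COLLAPSE = {
    ("G", "T"): "C>A", ("G", "C"): "C>G", ("G", "A"): "C>T",
    ("A", "T"): "T>A", ("A", "G"): "T>C", ("A", "C"): "T>G",
}

_VALID_CHARS = set("ACGT-")


def snv_class(ref_allele: str, alt_allele: str) -> str:
    """Collapse a single-base substitution to one of the six pyrimidine
    classes; indels and multi-base changes return 'non-SNV'."""
    for allele in (ref_allele, alt_allele):
        if not allele or set(allele) - _VALID_CHARS:
            raise ValueError(f"invalid allele string {allele!r}")
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        return "non-SNV"
    if "-" in (ref_allele, alt_allele) or ref_allele == alt_allele:
        return "non-SNV"
    if ref_allele in "CT":
        return f"{ref_allele}>{alt_allele}"
    return _COLLAPSE[(ref_allele, alt_allele)]


def mutation_frequency(
    maf: MafTable,
    genes: Sequence[str],
    cancer_type: str = "pan-cancer",
    include_silent: bool = False,
) -> pd.DataFrame:
    """Per-gene mutation frequency plus class and SNV spectra.

    A sample is mutated for a gene iff it carries at least one qualifying
    record for it (Silent excluded unless ``include_silent``), counted once
    regardless of how many variants it has. Output is sorted by descending
    frequency, ties broken by gene name; genes absent from the MAF get a
    zero row. Class and SNV spectrum columns count records (not samples),
    Silent included under its own label.
    """
    if not maf.cohort_samples:
        raise ValueError("MAF has an empty cohort sample universe")
    n_cohort = len(maf.cohort_samples)
    rec = maf.records
    rows = []
    for gene in genes:
        sub = rec[rec["Hugo_Symbol"] == gene]
        qualifying = sub if include_silent else sub[sub["Variant_Classification"] != "Silent"]
        n_mut = qualifying["Tumor_Sample_Barcode"].nunique()
        row = {
            "gene": gene,
            "cancer_type": cancer_type,
            "n_mutated_samples": int(n_mut),
            "n_cohort_samples": n_cohort,
            "frequency_pct": 100.0 * n_mut / n_cohort,
        }
        class_counts = sub["Variant_Classification"].value_counts()
        for cls in sorted(MAF_CLASSIFICATIONS):
            row[f"class_{cls}"] = int(class_counts.get(cls, 0))
        snv_counts = dict.fromkeys(SNV_CLASSES, 0)
        for ref, alt in zip(sub["Reference_Allele"], sub["Tumor_Seq_Allele2"]):
            cls = snv_class(ref, alt)
            if cls in snv_counts:
                snv_counts[cls] += 1
        for cls in SNV_CLASSES:
            row[f"snv_{cls}"] = snv_counts[cls]
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["frequency_pct", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def per_sample_summary(maf: MafTable) -> pd.DataFrame:
    """Variant counts per sample by classification, cohort-complete.

    Every cohort sample gets a row (zeros if unmutated); records are taken
    literally, so duplicated rows count twice. Counts partition the
    records: their grand total equals len(maf).
    """
    classes = sorted(MAF_CLASSIFICATIONS)
    table = pd.DataFrame(0, index=list(maf.cohort_samples), columns=classes)
    counts = (
        maf.records.groupby(["Tumor_Sample_Barcode", "Variant_Classification"])
        .size()
        .unstack(fill_value=0)
    )
    table.loc[counts.index, counts.columns] = counts
    table.index.name = "sample"
    return table


def oncoplot_matrix(maf: MafTable, genes: Sequence[str]) -> pd.DataFrame:
    """Gene x sample matrix of the most frequent classification per cell
    ('' where unmutated), the usual oncoplot input."""
    out = pd.DataFrame("", index=list(genes), columns=list(maf.cohort_samples))
    grouped = maf.records.groupby(["Hugo_Symbol", "Tumor_Sample_Barcode"])
    for (gene, sample), sub in grouped:
        if gene in out.index:
            out.loc[gene, sample] = sub["Variant_Classification"].mode().iloc[0]
    out.index.name = "gene"
    return out


def combine_maf(mafs: dict[str, MafTable]) -> MafTable:
    """Merge per-cancer MAFs into one pan-cancer table (sample universes
    concatenated; barcodes must not collide across cohorts)."""
    records = pd.concat([m.records for m in mafs.values()], ignore_index=True)
    samples: list[str] = []
    for m in mafs.values():
        samples.extend(m.cohort_samples)
    if len(set(samples)) != len(samples):
        raise ValueError("cohort sample universes overlap across cancers")
    return MafTable(records=records, cohort_samples=samples)
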