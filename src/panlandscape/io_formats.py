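"""Tabular I/O and TCGA-style barcode handling.

All omic layers travel as dense genes x samples TSV matrices with a declared
value semantics (raw counts, normalized expression, methylation beta, CNV
call, protein level, or drug AUC); somatic mutations travel as a standard
tab-separated MAF. Sample identity follows the TCGA barcode convention
(``PROJECT-TSS-PARTICIPANT-01A``), whose fourth field encodes the sample
type: codes 01-09 are tumor-derived, 10-19 normal-derived, 20-29 controls.
Barcode parsing is what lets the pipeline split tumor from normal and match
omic layers on the same participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleBarcode",
    "GeneSampleMatrix",
    "MafTable",
    "TumorNormalSplit",
    "MATRIX_SEMANTICS",
    "MAF_CLASSIFICATIONS",
    "MAF_COLUMNS",
    "BarcodeError",
    "MatrixValidationError",
    "MafValidationError",
    "parse_barcode",
    "match_tumor_normal",
    "read_matrix",
    "write_matrix",
    "read_maf",
    "write_maf",
]

MATRIX_SEMANTICS = (
    "raw_count",
    "normalized_expression",
    "beta",
    "cnv_call",
    "protein_level",
    "drug_auc",
)

#: Standard MAF variant-classification vocabulary accepted on read.
MAF_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Silent",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

MAF_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


class BarcodeError(ValueError):
    """Raised when a sample barcode cannot be parsed."""


class MatrixValidationError(ValueError):
    """Raised when a matrix violates its declared value semantics."""


class MafValidationError(ValueError):
    """Raised when a MAF violates the format contract."""


@dataclass(frozen=True)
class SampleBarcode:
    """Parsed TCGA-style sample barcode.

    ``participant`` joins the tissue-source-site and participant fields, so
    it uniquely identifies the patient; ``sample_code`` is the two-digit
    sample-type code from the fourth barcode field.
    """

    project: str
    participant: str
    sample_code: int
    vial: str | None = None

    @property
    def is_tumor(self) -> bool:
        return 1 <= self.sample_code <= 9

    @property
    def is_normal(self) -> bool:
        return 10 <= self.sample_code <= 19


def parse_barcode(raw: str) -> SampleBarcode:
    """Parse a dash-separated barcode into its typed fields.

    Accepts any barcode with >= 4 dash fields; the first two characters of
    the fourth field are the sample-type code, any trailing letters the
    vial. Extra fields (portion, plate, center) are ignored.
    """
    fields = str(raw).split("-")
    if len(fields) < 4:
        raise BarcodeError(
            f"barcode {raw!r} has {len(fields)} dash-separated fields, need >= 4"
        )
    for i, f_ in enumerate(fields[:4], start=1):
        if not f_:
            raise BarcodeError(f"barcode {raw!r}: field {i} is empty")
    sample_field = fields[3]
    code_part = sample_field[:2]
    if len(code_part) < 2 or not code_part.isdigit():
        raise BarcodeError(
            f"barcode {raw!r}: sample field {sample_field!r} does not start "
            "with a two-digit sample-type code"
        )
    vial = sample_field[2:] or None
    if vial is not None and not vial.isalpha():
        raise BarcodeError(
            f"barcode {raw!r}: vial suffix {vial!r} is not alphabetic"
        )
    return SampleBarcode(
        project=fields[0],
        participant="-".join(fields[1:3]),
        sample_code=int(code_part),
        vial=vial,
    )


class GeneSampleMatrix:
    """A genes x samples numeric table with declared value semantics.

    Thin wrapper over a :class:`pandas.DataFrame` (index = gene symbols,
    columns = sample barcodes or cell-line IDs) that enforces the semantics
    invariants on construction: beta values in [0, 1], CNV calls in
    {-2, -1, 0, 1, 2}, raw counts non-negative integers. Missing values
    (``NA`` on disk) are allowed everywhere except raw counts and propagate
    as NaN; downstream correlations are pairwise-complete.
    """

    def __init__(self, values: pd.DataFrame, semantics: str):
        if semantics not in MATRIX_SEMANTICS:
            raise MatrixValidationError(
                f"unknown semantics {semantics!r}; expected one of {MATRIX_SEMANTICS}"
            )
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene symbols: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate sample IDs: {dups}")
        values = values.astype(float)
        self._validate_values(values, semantics)
        self.values = values
        self.semantics = semantics

    @staticmethod
    def _validate_values(values: pd.DataFrame, semantics: str) -> None:
        arr = values.to_numpy()
        finite = arr[~np.isnan(arr)]
        if semantics == "raw_count":
            if np.isnan(arr).any():
                raise MatrixValidationError("raw_count matrix may not contain NA")
            if (finite < 0).any() or not np.allclose(finite, np.round(finite)):
                raise MatrixValidationError(
                    "raw_count matrix must hold non-negative integers"
                )
        elif semantics == "beta":
            if ((finite < 0) | (finite > 1)).any():
                bad = finite[(finite < 0) | (finite > 1)][0]
                raise MatrixValidationError(
                    f"beta matrix holds value {bad} outside [0, 1]"
                )
        elif semantics == "cnv_call":
            if not np.isin(finite, [-2.0, -1.0, 0.0, 1.0, 2.0]).all():
                bad = finite[~np.isin(finite, [-2.0, -1.0, 0.0, 1.0, 2.0])][0]
                raise MatrixValidationError(
                    f"cnv_call matrix holds value {bad} outside {{-2,-1,0,1,2}}"
                )

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    def subset_samples(self, samples: Sequence[str]) -> "GeneSampleMatrix":
        return GeneSampleMatrix(self.values.loc[:, list(samples)], self.semantics)

    def subset_genes(self, genes: Sequence[str]) -> "GeneSampleMatrix":
        return GeneSampleMatrix(self.values.loc[list(genes)], self.semantics)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSampleMatrix):
            return NotImplemented
        return self.semantics == other.semantics and self.values.equals(other.values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        g, s = self.values.shape
        return f"GeneSampleMatrix({g} genes x {s} samples, semantics={self.semantics!r})"


@dataclass(frozen=True)
class TumorNormalSplit:
    """Result of splitting a matrix's samples by barcode sample-type code."""

    tumors: tuple[str, ...]
    normals: tuple[str, ...]
    paired_participants: tuple[str, ...]


def match_tumor_normal(matrix: GeneSampleMatrix) -> TumorNormalSplit:
    """Split samples into tumor/normal and find matched participants.

    A participant appears in ``paired_participants`` iff it contributes both
    a tumor-derived and a normal-derived sample. Zero matched pairs is a
    warning, not an error (several TCGA cohorts have few normals).
    """
    tumors: list[str] = []
    normals: list[str] = []
    tumor_participants: set[str] = set()
    normal_participants: set[str] = set()
    for sample in matrix.samples:
        bc = parse_barcode(sample)
        if bc.is_tumor:
            tumors.append(sample)
            tumor_participants.add(bc.participant)
        elif bc.is_normal:
            normals.append(sample)
            normal_participants.add(bc.participant)
    pairs = tuple(sorted(tumor_participants & normal_participants))
    if not pairs:
        warnings.warn("no matched tumor/normal participant pairs found", stacklevel=2)
    return TumorNormalSplit(tuple(tumors), tuple(normals), pairs)


def read_matrix(path: str | Path, semantics: str) -> GeneSampleMatrix:
    """Read a dense TSV matrix (first column gene symbol, header = samples).

    Cells must be numeric or the literal ``NA``; a non-numeric cell raises
    with its gene/sample coordinates. Semantics invariants are enforced.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(lambda col: pd.to_numeric(col.replace({"NA": None}), errors="coerce"))
    bad = numeric.isna() & ~raw.isin(["NA", ""])
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise MatrixValidationError(
            f"non-numeric cell {raw.iat[gi, si]!r} at gene {raw.index[gi]!r}, "
            f"sample {raw.columns[si]!r} in {path}"
        )
    return GeneSampleMatrix(numeric, semantics)


def write_matrix(matrix: GeneSampleMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing values serialize as ``NA``.

    Uses full float repr so write-then-read round-trips exactly.
    """
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class MafTable:
    """Somatic mutation records plus the full cohort sample universe.

    ``records`` is a DataFrame with the five standard MAF columns;
    ``cohort_samples`` lists every sample in the cohort, so samples with
    zero mutations still count in frequency denominators.
    """

    records: pd.DataFrame
    cohort_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in MAF_COLUMNS if c not in self.records.columns]
        if missing:
            raise MafValidationError(f"MAF is missing required column(s): {missing}")
        self.records = self.records.loc[:, list(MAF_COLUMNS)].reset_index(drop=True)
        bad_class = set(self.records["Variant_Classification"]) - MAF_CLASSIFICATIONS
        if bad_class:
            raise MafValidationError(
                f"unknown Variant_Classification token(s) {sorted(bad_class)}; "
                f"allowed: {sorted(MAF_CLASSIFICATIONS)}"
            )
        universe = set(self.cohort_samples)
        stray = set(self.records["Tumor_Sample_Barcode"]) - universe
        if stray:
            raise MafValidationError(
                f"MAF sample(s) not in cohort_samples: {sorted(stray)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)


def read_maf(path: str | Path, cohort_samples: Iterable[str]) -> MafTable:
    """Read a tab-separated MAF, keeping every record (Silent included).

    Filtering of silent variants happens downstream in the mutation
    summaries, never at parse time.
    """
    records = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return MafTable(records=records, cohort_samples=list(cohort_samples))


def write_maf(maf: MafTable, path: str | Path) -> None:
    maf.records.to_csv(path, sep="\t", index=False)
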