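"""Readers and writers for the pipeline's tabular inputs.

Expression matrices are kept as pandas DataFrames (genes as rows, samples as
columns) holding ``log2(TPM + 0.001)`` values; mutation tables and clinical
tables are tidy DataFrames. Genesets come from standard GMT files.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: pseudo-count floor on the log2 scale: log2(0 + 0.001)
LOG2_FLOOR: float = float(np.log2(0.001))

#: standard MAF variant-classification vocabulary
MAF_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Silent",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (order-preserving, unique)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("geneset name must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            # keep first occurrence of each gene
            seen: dict[str, None] = {}
            for g in self.genes:
                seen.setdefault(g)
            object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Apply the ``log2(TPM + 0.001)`` transform used throughout the pipeline."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return np.log2(tpm + 0.001)


def read_expression(path: str | Path, already_log_transformed: bool = False) -> pd.DataFrame:
    """Read a genes-by-samples expression TSV.

    Parameters
    ----------
    path
        Tab-separated file, genes as rows, first column gene ids, header row
        of sample ids.
    already_log_transformed
        If True the file already stores log2(TPM + 0.001) and values pass
        through unchanged; otherwise values are TPM and are transformed.

    Duplicate gene rows are resolved by first occurrence. Duplicate sample
    columns and missing or non-numeric cells are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    counts = Counter(header)
    dups = sorted(s for s, k in counts.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate sample id(s) in header: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        raw = raw.loc[~raw.index.duplicated(keep="first")]
    try:
        mat = raw.astype(float)
    except ValueError:
        # locate the offending cell for a useful message
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}"
                ) from None
        raise
    if mat.isna().to_numpy().any():
        col = mat.columns[mat.isna().any(axis=0)][0]
        row = mat.index[mat[col].isna()][0]
        raise ValueError(f"missing expression value at gene {row!r}, sample {col!r}")
    if already_log_transformed:
        return mat
    return log_transform(mat)


def dedup_samples(matrix: pd.DataFrame, patient_map: Mapping[str, str]) -> pd.DataFrame:
    """Keep one sample per patient: the one with the highest median expression.

    Ties in median are broken by file (column) order. Samples missing from
    ``patient_map`` are treated as their own patient.
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    medians = matrix.median(axis=0)
    keep: list[str] = []
    best: dict[str, tuple[float, str]] = {}
    order: list[str] = []
    for sample in matrix.columns:
        patient = patient_map.get(sample, sample)
        med = float(medians[sample])
        if patient not in best:
            best[patient] = (med, sample)
            order.append(patient)
        elif med > best[patient][0]:  # strict: first occurrence wins ties
            best[patient] = (med, sample)
    keep = [best[p][1] for p in order]
    return matrix.loc[:, keep]


def read_genesets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one geneset per line, ``name<TAB>description<TAB>genes...``."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"malformed GMT line {lineno}: no member genes")
            sets.append(GeneSet(name=name, genes=tuple(genes), description=desc))
    return sets


def write_genesets(genesets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF-style tab-separated mutation table.

    Requires Tumor_Sample_Barcode, Hugo_Symbol and Variant_Classification
    columns; other columns are carried along. Unknown variant-classification
    strings are preserved but flagged with a warning.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"MAF file missing required column(s): {missing}")
    unknown = sorted(set(table["Variant_Classification"]) - MAF_CLASSES)
    if unknown:
        warnings.warn(
            f"unknown variant classification(s) preserved: {unknown}", stacklevel=2
        )
    return table


CLINICAL_TIME_COLUMNS = ("ttp_days", "os_days", "treatment_duration_days")
CLINICAL_EVENT_COLUMNS = ("ttp_event", "os_event")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical/annotation TSV (one row per sample).

    Survival times are day offsets from treatment start and must be
    nonnegative; event indicators must be 0/1. Optional columns (mantis,
    hrd_score, msisensor, hrdetect, dcb, ...) pass through.
    """
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns:
        raise ValueError("clinical table requires a sample_id column")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s) in clinical table: {dups}")
    for col in CLINICAL_TIME_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="raise")
            if (vals.dropna() < 0).any():
                raise ValueError(f"negative time in clinical column {col!r}")
    for col in CLINICAL_EVENT_COLUMNS:
        if col in table.columns:
            vals = table[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"event column {col!r} must be binary 0/1")
    return table


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a tidy result table as TSV with header."""
    table.to_csv(path, sep="\t", index=index)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes-by-samples matrix of log2(TPM + 0.001) values as TSV."""
    matrix.to_csv(path, sep="\t", index_label="gene_id")
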