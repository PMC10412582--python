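"""The 4-chemokine c-Score and quartile-based group stratification.

The c-Score of a sample is the arithmetic mean of its log2(TPM + 0.001)
expression of CCL4, CCL5, CXCL9 and CXCL10. Samples at or above the cohort
third quartile are ``hi``, at or below the first quartile ``lo``, otherwise
``med``. Thresholds may be the fixed pan-cancer defaults or derived from the
cohort at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: the four signature chemokines
CHEMOKINES: tuple[str, ...] = ("CCL4", "CCL5", "CXCL9", "CXCL10")

GROUPS = ("hi", "med", "lo")
POOLED_REFERENCE = "lo+med"


@dataclass(frozen=True)
class StratificationThresholds:
    """First/third-quartile c-Score cutoffs and where they came from."""

    q1: float
    q3: float
    source: str = "cohort-relative"

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError(f"q1 ({self.q1}) must be <= q3 ({self.q3})")


#: fixed pan-cancer defaults derived from the 6987-sample TCGA discovery cohort
TCGA_THRESHOLDS = StratificationThresholds(q1=1.940425, q3=4.835088, source="fixed")


def compute_cscore(matrix: pd.DataFrame, genes: Sequence[str] = CHEMOKINES) -> pd.Series:
    """Per-sample mean of the stored log2(TPM + 0.001) chemokine values.

    Raises
    ------
    KeyError
        If any signature gene is absent from the matrix (named in the message).
    """
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"chemokine gene(s) absent from expression matrix: {missing}")
    scores = matrix.loc[list(genes)].mean(axis=0)
    scores.name = "c_score"
    return scores


def derive_thresholds(scores: Iterable[float]) -> StratificationThresholds:
    """Cohort-relative Q1/Q3 by linear interpolation between order statistics."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 scores to derive quartiles, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return StratificationThresholds(q1=float(q1), q3=float(q3), source="cohort-relative")


def stratify(
    scores: pd.Series,
    thresholds: StratificationThresholds,
    tumor_types: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign hi/med/lo groups: hi tested first (>= q3), then lo (<= q1), else med.

    Returns a per-sample table with c_score, group and (if given) tumor_type.
    """
    vals = scores.to_numpy(dtype=float)
    group = np.where(vals >= thresholds.q3, "hi", np.where(vals <= thresholds.q1, "lo", "med"))
    out = pd.DataFrame({"c_score": scores, "group": pd.Categorical(group, categories=GROUPS)})
    out["q1"] = thresholds.q1
    out["q3"] = thresholds.q3
    out["threshold_source"] = thresholds.source
    if tumor_types is not None:
        out["tumor_type"] = tumor_types.reindex(scores.index)
    return out


def filter_tumor_types(stratified: pd.DataFrame, min_per_group: int = 5) -> list[str]:
    """Tumor types with at least ``min_per_group`` samples in each of hi/med/lo."""
    if "tumor_type" not in stratified.columns:
        raise ValueError("stratified cohort lacks a tumor_type column")
    counts = (
        stratified.groupby("tumor_type", observed=True)["group"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(GROUPS), fill_value=0)
    )
    included = counts.index[(counts >= min_per_group).all(axis=1)]
    return sorted(included)


def pool_groups(groups: pd.Series) -> pd.Series:
    """Collapse med and lo into the pooled lo+med reference group."""
    vals = groups.astype(str)
    bad = set(vals.unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    pooled = vals.where(vals == "hi", POOLED_REFERENCE)
    pooled.name = "pooled_group"
    return pooled
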