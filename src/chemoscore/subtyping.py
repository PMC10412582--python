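"""MSI/HRD genomic subtyping and TMB-association classification.

Subtypes are assigned from precomputed scores: MANTIS (microsatellite
instability; hi if strictly > 0.4), HRDScore (homologous-recombination
deficiency; hi if >= 46 in BRCA/OV, >= 27 elsewhere) and MSIsensor (hi if
strictly > 0.2). When a tumor is high for both MANTIS and HRDScore the MSI
call takes precedence. Missing scores classify as low.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import POOLED_REFERENCE, pool_groups

MANTIS_CUTOFF = 0.4  # strict >
MSISENSOR_CUTOFF = 0.2  # strict >

#: fixed HRDScore third-quartile cutoffs (BRCA/OV stratum, rest of cohort)
FIXED_HRD_THRESHOLDS: tuple[float, float] = (46.0, 27.0)
BRCA_OV_TYPES: frozenset[str] = frozenset({"BRCA", "OV"})


def classify_mantis(scores: pd.Series) -> pd.Series:
    """'hi' iff MANTIS > 0.4 (strict); missing scores are 'lo'."""
    vals = pd.to_numeric(scores, errors="coerce")
    if (vals.dropna() < 0).any():
        raise ValueError("MANTIS scores must be nonnegative")
    out = pd.Series(np.where(vals > MANTIS_CUTOFF, "hi", "lo"), index=scores.index)
    out.name = "mantis_class"
    return out


def classify_msisensor(scores: pd.Series) -> pd.Series:
    """'hi' iff MSIsensor > 0.2 (strict); missing scores are 'lo'."""
    vals = pd.to_numeric(scores, errors="coerce")
    out = pd.Series(np.where(vals > MSISENSOR_CUTOFF, "hi", "lo"), index=scores.index)
    out.name = "msisensor_class"
    return out


def hrd_thresholds(
    scores: pd.Series,
    tumor_types: pd.Series,
    brca_ov: frozenset[str] = BRCA_OV_TYPES,
) -> tuple[float, float]:
    """Third-quartile HRDScore cutoffs computed separately for the BRCA/OV
    stratum and the remainder of the cohort (linear-interpolation quartiles).
    """
    vals = pd.to_numeric(scores, errors="coerce")
    in_stratum = tumor_types.reindex(vals.index).isin(brca_ov)
    strat = vals[in_stratum].dropna()
    rest = vals[~in_stratum].dropna()
    if strat.empty or rest.empty:
        raise ValueError("both the BRCA/OV stratum and the remainder must be nonempty")
    return float(np.quantile(strat, 0.75)), float(np.quantile(rest, 0.75))


def classify_hrd(
    scores: pd.Series,
    tumor_types: pd.Series,
    thresholds: tuple[float, float] = FIXED_HRD_THRESHOLDS,
    brca_ov: frozenset[str] = BRCA_OV_TYPES,
) -> pd.Series:
    """'hi' iff HRDScore >= the stratum cutoff (inclusive); missing -> 'lo'."""
    vals = pd.to_numeric(scores, errors="coerce")
    cutoff = np.where(tumor_types.reindex(vals.index).isin(brca_ov), thresholds[0], thresholds[1])
    hi = vals.to_numpy() >= cutoff  # NaN compares False
    out = pd.Series(np.where(hi, "hi", "lo"), index=scores.index)
    out.name = "hrd_class"
    return out


def resolve_subtype(
    cscore_group: pd.Series,
    mantis_class: pd.Series,
    hrd_class: pd.Series,
) -> pd.Series:
    """Resolve each sample to exactly one subtype label.

    Precedence: MANTIS^hi (whatever the HRD call) > HRDScore^hi > the pooled
    c-Score label (c-Score^hi or c-Score^lo+med).
    """
    pooled = pool_groups(cscore_group)
    labels = np.where(
        mantis_class.reindex(pooled.index) == "hi",
        "MANTIS^hi",
        np.where(
            hrd_class.reindex(pooled.index) == "hi",
            "HRDScore^hi",
            np.where(pooled == "hi", "c-Score^hi", f"c-Score^{POOLED_REFERENCE}"),
        ),
    )
    out = pd.Series(labels, index=pooled.index, name="resolved_subtype")
    return out


def classify_tmb_association(
    tmb: pd.Series,
    stratified: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag tumor types where c-Score^hi tumors carry higher TMB.

    Per type, a two-sided Wilcoxon rank-sum test compares TMB between the hi
    and pooled lo+med groups; P values are BH-FDR adjusted across types. A
    type is 'associated' iff adjusted P < alpha and the hi-group median TMB
    exceeds the lo+med median. Types with an empty group are 'unassociated'
    with a warning.
    """
    pooled = pool_groups(stratified["group"])
    df = pd.DataFrame(
        {
            "tmb": tmb.reindex(stratified.index),
            "pooled": pooled,
            "tumor_type": stratified["tumor_type"],
        }
    )
    rows = []
    for ttype, sub in df.groupby("tumor_type", observed=True):
        hi = sub.loc[sub["pooled"] == "hi", "tmb"].dropna()
        ref = sub.loc[sub["pooled"] == POOLED_REFERENCE, "tmb"].dropna()
        if len(hi) < 2 or len(ref) < 2:
            warnings.warn(
                f"tumor type {ttype!r} has an empty or tiny group; marked unassociated",
                stacklevel=2,
            )
            rows.append(
                {
                    "tumor_type": ttype,
                    "n_hi": len(hi),
                    "n_ref": len(ref),
                    "median_hi": hi.median() if len(hi) else np.nan,
                    "median_ref": ref.median() if len(ref) else np.nan,
                    "statistic": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        stat, p = stats.mannwhitneyu(hi, ref, alternative="two-sided")
        rows.append(
            {
                "tumor_type": ttype,
                "n_hi": len(hi),
                "n_ref": len(ref),
                "median_hi": float(hi.median()),
                "median_ref": float(ref.median()),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("tumor_type")
    tested = out["p_value"].notna()
    adjusted = pd.Series(np.nan, index=out.index)
    if tested.any():
        adjusted[tested] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["p_adjusted"] = adjusted
    out["direction_hi_higher"] = out["median_hi"] > out["median_ref"]
    out["association"] = np.where(
        (out["p_adjusted"] < alpha) & out["direction_hi_higher"],
        "associated",
        "unassociated",
    )
    return out


def cross_tabulate(
    labels_a: pd.Series,
    labels_b: pd.Series,
    test: str = "fisher",
) -> dict:
    """Contingency table of two label series with an association test.

    ``test='fisher'`` requires a 2x2 table (two-sided exact P);
    ``test='chi2'`` runs Pearson chi-squared without continuity correction.
    Returns counts, row proportions, the statistic (chi2 only) and P.
    """
    table = pd.crosstab(labels_a, labels_b)
    counts = table.to_numpy()
    result: dict = {
        "table": table,
        "proportions": table.div(table.sum(axis=1), axis=0),
    }
    if test == "fisher":
        if counts.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(counts, alternative="two-sided")
        result.update(statistic=float(odds), p_value=float(p), test="fisher")
    elif test == "chi2":
        chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
        result.update(statistic=float(chi2), p_value=float(p), dof=int(dof), test="chi2")
    else:
        raise ValueError(f"unknown test {test!r}")
    return result
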