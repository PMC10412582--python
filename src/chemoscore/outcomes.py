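"""Clinical-outcome analysis: DCB, Kaplan-Meier/log-rank, Cox PH, and
covariate-controlled group comparisons.

Time to progression (TTP) runs from treatment initiation to discontinuation
due to progression; overall survival (OS) from initiation to death. Durable
clinical benefit (DCB) is treatment for more than six months (183 days)
without progression in that window. Survival times are in days throughout.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

DCB_CUTOFF_DAYS = 183  # six months; benefit requires strictly longer treatment


def derive_dcb(treatment_duration_days, progressed_within) -> pd.Series | str:
    """DCB iff treatment exceeded 183 days with no progression in that window.

    Accepts scalars or aligned array-likes; returns 'DCB'/'NCB'.
    """
    duration = np.asarray(treatment_duration_days, dtype=float)
    progressed = np.asarray(progressed_within, dtype=bool)
    labels = np.where((duration > DCB_CUTOFF_DAYS) & ~progressed, "DCB", "NCB")
    if labels.ndim == 0:
        return str(labels)
    index = getattr(treatment_duration_days, "index", None)
    return pd.Series(labels, index=index, name="dcb")


def response_rates(dcb_labels: pd.Series, groups: pd.Series) -> dict:
    """Per-group DCB rate table with a chi-squared test of association.

    The chi-squared statistic is Pearson's without continuity correction on
    the groups-by-outcome contingency table.
    """
    df = pd.DataFrame({"dcb": dcb_labels.astype(str), "group": groups.astype(str)})
    table = pd.crosstab(df["group"], df["dcb"]).reindex(columns=["DCB", "NCB"], fill_value=0)
    rates = pd.DataFrame(
        {
            "n_dcb": table["DCB"],
            "n_total": table.sum(axis=1),
        }
    )
    rates["rate"] = rates["n_dcb"] / rates["n_total"]
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"rates": rates, "table": table, "statistic": float(chi2), "p_value": float(p), "dof": int(dof)}


def km_logrank(time: pd.Series, event: pd.Series, groups: pd.Series) -> dict:
    """Kaplan-Meier curves per group with log-rank comparison.

    Returns fitted curves, per-group median survival (NaN when the curve
    never reaches 0.5, reported as not-reached) and the two-group or k-group
    log-rank P.
    """
    df = pd.DataFrame({"time": time, "event": event, "group": groups.astype(str)}).dropna()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for name, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=name)
        curves[name] = kmf.survival_function_
        med = kmf.median_survival_time_
        medians[name] = float(med) if np.isfinite(med) else float("nan")
    names = sorted(curves)
    if len(names) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    if len(names) == 2:
        a = df[df["group"] == names[0]]
        b = df[df["group"] == names[1]]
        res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    else:
        res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return {
        "curves": curves,
        "medians": medians,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
    }


def cox_ph(
    records: pd.DataFrame,
    duration_col: str,
    event_col: str,
    terms: Sequence[str],
    tumor_type_col: str | None = None,
    min_type_count: int = 3,
) -> dict:
    """Cox proportional-hazards fit (Efron tie handling, partial likelihood).

    Categorical terms are one-hot encoded (first level as reference). When a
    tumor-type term is included, only types with at least ``min_type_count``
    patients enter the model. Returns per-term hazard ratios with Wald 95% CI
    and P, plus the model likelihood-ratio P. Constant covariates raise;
    non-convergence or separation is surfaced as a flagged result.
    """
    cols = [duration_col, event_col, *terms]
    df = records[cols].dropna().copy()
    if tumor_type_col is not None and tumor_type_col in terms:
        counts = df[tumor_type_col].value_counts()
        keep = counts.index[counts >= min_type_count]
        df = df[df[tumor_type_col].isin(keep)]
    X = pd.get_dummies(df, columns=[t for t in terms if df[t].dtype == object], drop_first=True)
    X = X.astype(float)
    covariates = [c for c in X.columns if c not in (duration_col, event_col)]
    for c in covariates:
        if X[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant; no information")
    fitter = CoxPHFitter()  # lifelines uses the Efron approximation for ties
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                X,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"precision": 1e-11, "max_steps": 500},
            )
    except Exception as exc:  # separation / non-convergence
        return {"converged": False, "error": str(exc), "summary": None, "lr_p_value": float("nan")}
    summary = fitter.summary[["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summary = summary.rename(
        columns={
            "exp(coef)": "hazard_ratio",
            "exp(coef) lower 95%": "ci_lower",
            "exp(coef) upper 95%": "ci_upper",
            "p": "p_value",
        }
    )
    lr = fitter.log_likelihood_ratio_test()
    return {
        "converged": True,
        "summary": summary,
        "lr_p_value": float(lr.p_value),
        "n": int(X.shape[0]),
        "model": fitter,
    }


def group_compare(values: pd.Series, groups: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum comparison between exactly two groups."""
    df = pd.DataFrame({"v": values, "g": groups.astype(str)}).dropna()
    names = sorted(df["g"].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a = df.loc[df["g"] == names[0], "v"]
    b = df.loc[df["g"] == names[1], "v"]
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "groups": names,
        "statistic": float(stat),
        "p_value": float(p),
        "medians": {names[0]: float(a.median()), names[1]: float(b.median())},
        "direction": names[0] if a.median() > b.median() else names[1],
    }


def adjust_fdr(raw_ps: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    arr = np.asarray(list(raw_ps), dtype=float)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def controlled_compare(
    response: pd.Series,
    group: pd.Series,
    covariates: pd.DataFrame | pd.Series | None = None,
) -> dict:
    """Group effect on a response, controlling for covariates via OLS.

    The group is entered as an indicator of its second (sorted) level;
    categorical covariates are one-hot encoded. Returns the group coefficient
    and its P value.
    """
    df = pd.DataFrame({"response": pd.to_numeric(response), "group": group.astype(str)})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"need a binary group, got {levels}")
    df["group_ind"] = (df["group"] == levels[1]).astype(float)
    X = df[["group_ind"]]
    if covariates is not None:
        cov = covariates.to_frame() if isinstance(covariates, pd.Series) else covariates.copy()
        cov = cov.reindex(df.index)
        cat = [c for c in cov.columns if cov[c].dtype == object]
        cov = pd.get_dummies(cov, columns=cat, drop_first=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(df["response"], X, missing="drop").fit()
    return {
        "group_levels": levels,
        "estimate": float(fit.params["group_ind"]),
        "p_value": float(fit.pvalues["group_ind"]),
        "model": fit,
    }


def correlate_medians(x: pd.Series, y: pd.Series) -> dict:
    """Spearman rank correlation of two aligned per-type summary vectors."""
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    rho, p = stats.spearmanr(df["x"], df["y"])
    return {"rho": float(rho), "p_value": float(p), "n": int(len(df))}
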