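"""Single-sample geneset enrichment (ssGSEA) and the arbitrary-unit transform.

The per-sample enrichment score is the rank-weighted running-sum statistic:
genes are ranked within each sample (rank 1 = lowest expression, rank G =
highest, ties averaged) and walked in order of decreasing expression. In-set
genes advance a weighted empirical CDF with weight rank**tau; out-of-set
genes advance a uniform ECDF. The score is the sum over all positions of the
difference between the two running CDFs. Scores are optionally normalized by
the (max - min) range over the whole geneset-by-sample table.

For display on a positive scale, group-median enrichment scores are
translated into arbitrary units (AU) pinned so that the reference
(c-Score lo+med) group's AU equals 1 for every geneset; statistics are always
computed on untransformed scores.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LOG2_FLOOR, GeneSet
from .scoring import CHEMOKINES, POOLED_REFERENCE

DEFAULT_TAU = 0.25
_ZERO_TOL = 1e-9


def filter_expressed_genes(
    matrix: pd.DataFrame, max_zero_fraction: float = 0.5
) -> pd.DataFrame:
    """Drop genes with zero TPM in strictly more than ``max_zero_fraction`` of samples.

    A stored value equal to log2(0.001) marks zero TPM.
    """
    zero = matrix.to_numpy() <= LOG2_FLOOR + _ZERO_TOL
    frac = zero.mean(axis=1)
    return matrix.loc[frac <= max_zero_fraction]


def prepare_genesets(
    genesets: Sequence[GeneSet], exclude: Sequence[str] = CHEMOKINES
) -> list[GeneSet]:
    """Remove the signature chemokines from each geneset before enrichment.

    Genesets emptied by the removal are dropped with a warning.
    """
    out: list[GeneSet] = []
    excluded = set(exclude)
    for gs in genesets:
        genes = tuple(g for g in gs.genes if g not in excluded)
        if not genes:
            warnings.warn(f"geneset {gs.name!r} empty after chemokine removal; dropped", stacklevel=2)
            continue
        out.append(GeneSet(name=gs.name, genes=genes, description=gs.description))
    return out


def _ssgsea_raw_sample(values: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Raw enrichment score of one sample (vectorized running-sum statistic)."""
    g = values.size
    ranks = stats.rankdata(values)  # 1 = lowest expression, ties averaged
    # walk genes by decreasing expression; stable tie-break by input position
    order = np.lexsort((np.arange(g), -values))
    ranks_ord = ranks[order]
    in_ord = in_set[order]
    n_in = int(in_set.sum())
    n_out = g - n_in
    weights = np.where(in_ord, np.abs(ranks_ord) ** tau, 0.0)
    denom = weights.sum()
    cdf_in = np.cumsum(weights) / denom
    cdf_out = np.cumsum(~in_ord) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea(
    matrix: pd.DataFrame,
    geneset: GeneSet,
    tau: float = DEFAULT_TAU,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample enrichment score for one geneset.

    When ``normalize`` is set, scores are divided by the (max - min) range of
    this run's scores. For multi-geneset runs normalized over the whole table
    use :func:`enrichment_table`.
    """
    raw = _ssgsea_scores(matrix, geneset, tau)
    if normalize:
        raw = _range_normalize(raw.to_frame().T).iloc[0]
    raw.name = geneset.name
    return raw


def _ssgsea_scores(matrix: pd.DataFrame, geneset: GeneSet, tau: float) -> pd.Series:
    members = [g for g in geneset.genes if g in matrix.index]
    if not members:
        raise ValueError(f"geneset {geneset.name!r} shares no genes with the matrix")
    if len(members) == matrix.shape[0]:
        raise ValueError(f"geneset {geneset.name!r} covers every gene (empty out-set)")
    in_set = matrix.index.isin(members)
    vals = matrix.to_numpy(dtype=float)
    scores = np.array(
        [_ssgsea_raw_sample(vals[:, j], in_set, tau) for j in range(vals.shape[1])]
    )
    return pd.Series(scores, index=matrix.columns, name=geneset.name)


def _range_normalize(table: pd.DataFrame) -> pd.DataFrame:
    span = float(table.to_numpy().max() - table.to_numpy().min())
    if span == 0.0:
        return table
    return table / span


def enrichment_table(
    matrix: pd.DataFrame,
    genesets: Sequence[GeneSet],
    tau: float = DEFAULT_TAU,
    normalize: bool = True,
) -> pd.DataFrame:
    """Geneset-by-sample enrichment score table.

    Normalization divides every score by the (max - min) range across the
    whole table, so relative geneset contrasts are preserved.
    """
    rows = [_ssgsea_scores(matrix, gs, tau) for gs in genesets]
    table = pd.DataFrame(rows)
    table.index.name = "geneset"
    table.attrs["tau"] = tau
    table.attrs["normalized"] = normalize
    if normalize:
        table = _range_normalize(table)
    return table


def au_transform(scores: pd.DataFrame, pooled_groups: pd.Series) -> pd.DataFrame:
    """Translate group-median enrichment scores to arbitrary units (AU).

    For geneset j and group i, AU_ji = 1 + (median_i - median_ref) where the
    reference group is the pooled c-Score lo+med group, whose AU is therefore
    exactly 1 for every geneset. The between-group median difference is
    preserved exactly. Statistics belong on the untransformed scores.
    """
    pooled = pooled_groups.astype(str)
    group_names = list(dict.fromkeys(pooled))
    if POOLED_REFERENCE not in group_names:
        raise ValueError(f"reference group {POOLED_REFERENCE!r} not present")
    rows = []
    for geneset, values in scores.iterrows():
        medians = {}
        for name in group_names:
            members = pooled.index[pooled == name]
            vals = values.reindex(members).dropna()
            if vals.empty:
                raise ValueError(f"group {name!r} empty for geneset {geneset!r}")
            medians[name] = float(vals.median())
        ref = medians[POOLED_REFERENCE]
        for name in group_names:
            rows.append(
                {
                    "geneset": geneset,
                    "group": name,
                    "median_score": medians[name],
                    "au": 1.0 + (medians[name] - ref),
                }
            )
    return pd.DataFrame(rows)
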