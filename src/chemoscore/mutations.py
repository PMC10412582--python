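"""Per-sample tumor mutational burden (TMB) and mutation-based metrics.

TMB is counted non-silent mutations divided by the exome capture size in
megabases (default 35.8 Mb); samples at or above 10 mutations/Mb are TMB^hi.
Also provides the protein-truncating classification, DNA-repair pathway
mutation rates, and KRAS mutation status.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MAF_CLASSES

#: classes excluded from TMB counting (non-silent convention)
SILENT_CLASSES: frozenset[str] = frozenset(
    {"Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "IGR", "RNA", "Targeted_Region"}
)

#: default counted classes: every known MAF class that is not silent/non-coding
NONSILENT_CLASSES: frozenset[str] = MAF_CLASSES - SILENT_CLASSES

#: the six protein-truncating variant classes
TRUNCATING_CLASSES: frozenset[str] = frozenset(
    {
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Nonsense_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: DNA repair and fidelity pathway gene sets
PATHWAY_GENES: dict[str, frozenset[str]] = {
    "mmr": frozenset({"MLH1", "MSH2", "MSH6", "PMS2"}),
    "hr": frozenset({"BRCA1", "BRCA2", "PALB2"}),
    "replication": frozenset({"POLE", "POLD1"}),
}

DEFAULT_CAPTURE_MB = 35.8
TMB_HI_CUTOFF = 10.0

_warned_classes: set[str] = set()


def is_protein_truncating(variant_classification: str) -> bool:
    """True exactly for the six protein-truncating MAF classes.

    Unknown classification strings never count as truncating; each distinct
    unknown string triggers a single warning.
    """
    if variant_classification in TRUNCATING_CLASSES:
        return True
    if variant_classification not in MAF_CLASSES and variant_classification not in _warned_classes:
        _warned_classes.add(variant_classification)
        warnings.warn(
            f"unknown variant classification {variant_classification!r} treated as non-truncating",
            stacklevel=2,
        )
    return False


def compute_tmb(
    maf: pd.DataFrame,
    samples: Sequence[str] | None = None,
    capture_size_mb: float = DEFAULT_CAPTURE_MB,
    counted_classes: Iterable[str] = NONSILENT_CLASSES,
) -> pd.DataFrame:
    """Mutations per megabase for each sample, with the TMB^hi flag.

    Parameters
    ----------
    maf
        MAF-style table (Tumor_Sample_Barcode, Variant_Classification, ...).
    samples
        Full cohort sample list; samples absent from the table get 0 counted
        mutations. Defaults to the samples present in the table.
    capture_size_mb
        Exome capture size in megabases.
    counted_classes
        Variant classes included in the count (default: non-silent).

    Returns a table indexed by sample with counted_mutations, tmb and
    tmb_class ('hi' iff tmb >= 10, inclusive).
    """
    if capture_size_mb <= 0:
        raise ValueError("capture size must be positive")
    counted = frozenset(counted_classes)
    sel = maf[maf["Variant_Classification"].isin(counted)]
    counts = sel.groupby("Tumor_Sample_Barcode").size()
    if samples is None:
        samples = maf["Tumor_Sample_Barcode"].unique()
    counts = counts.reindex(samples, fill_value=0).astype(int)
    tmb = counts / capture_size_mb
    out = pd.DataFrame(
        {
            "counted_mutations": counts,
            "capture_size_mb": capture_size_mb,
            "tmb": tmb,
            "tmb_class": np.where(tmb >= TMB_HI_CUTOFF, "hi", "lo"),
        }
    )
    out.index.name = "sample_id"
    return out


def pathway_mutation_rates(
    maf: pd.DataFrame,
    groups: pd.Series,
    pathway_genes: Mapping[str, frozenset[str]] = PATHWAY_GENES,
    truncating_only: bool = False,
) -> pd.DataFrame:
    """Mutation burden of DNA repair/fidelity pathway genes per sample group.

    For each (group, pathway): ``count_rate`` is the number of qualifying
    mutation records divided by the number of patients in the group;
    ``patient_fraction`` is the fraction of patients carrying at least one
    qualifying mutation. ``truncating_only`` restricts to the six
    protein-truncating classes.
    """
    groups = groups.astype(str)
    table = maf
    if truncating_only:
        table = table[table["Variant_Classification"].isin(TRUNCATING_CLASSES)]
    rows = []
    for pathway, genes in pathway_genes.items():
        hits = table[table["Hugo_Symbol"].isin(genes)]
        hit_counts = hits.groupby("Tumor_Sample_Barcode").size()
        for group_name, members in groups.groupby(groups):
            ids = members.index
            n = len(ids)
            in_group = hit_counts.reindex(ids, fill_value=0)
            rows.append(
                {
                    "group": group_name,
                    "pathway": pathway,
                    "n_patients": n,
                    "count_rate": in_group.sum() / n if n else 0.0,
                    "patient_fraction": (in_group > 0).mean() if n else 0.0,
                    "truncating_only": truncating_only,
                }
            )
    return pd.DataFrame(rows)


def kras_status(
    maf: pd.DataFrame,
    samples: Sequence[str],
    tumor_types: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-sample KRAS status: mutated iff >=1 non-silent KRAS record.

    Returns the per-sample 'wt'/'mutated' series and, when tumor types are
    given, a per-type prevalence table.
    """
    kras = maf[
        (maf["Hugo_Symbol"] == "KRAS")
        & maf["Variant_Classification"].isin(NONSILENT_CLASSES)
    ]
    mutated_ids = set(kras["Tumor_Sample_Barcode"])
    status = pd.Series(
        ["mutated" if s in mutated_ids else "wt" for s in samples],
        index=pd.Index(samples, name="sample_id"),
        name="kras_status",
    )
    prevalence = None
    if tumor_types is not None:
        df = pd.DataFrame({"status": status, "tumor_type": tumor_types.reindex(status.index)})
        prevalence = (
            df.groupby("tumor_type", observed=True)["status"]
            .apply(lambda s: (s == "mutated").mean())
            .rename("kras_prevalence")
            .reset_index()
        )
    return status, prevalence
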