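"""Seeded synthetic multi-tumor-type cohorts for exercising the pipeline.

The generator emulates the statistical structure the analysis assumes:

* a per-sample latent inflammation factor (standard normal around a
  tumor-type mean) that co-drives the four signature chemokines and the
  immune-geneset genes on the log2 expression scale (log-normal TPMs);
* a minority of "cold" tumor types with strongly depressed inflammation, so
  they fail the >=5-patients-per-group inclusion filter;
* per-type negative-binomial mutation loads, inflated in MSI samples and —
  in the planted "TMB-associated" types — in inflammation-high samples;
* minority MSI and HRD subpopulations with MANTIS / HRDScore / MSIsensor
  values consistent with their planted membership;
* exponential TTP and OS with a planted hazard ratio for the
  inflammation-high group, independent exponential censoring, and durable
  clinical benefit labels with group-dependent probabilities.

Identical configurations (same seed) produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LOG2_FLOOR, GeneSet, write_genesets
from .scoring import CHEMOKINES, compute_cscore, derive_thresholds, pool_groups, stratify

#: cancer-immunity-cycle genesets used by default (chemokines intentionally
#: present in two sets so geneset preparation has something to remove)
DEFAULT_GENESETS: tuple[GeneSet, ...] = (
    GeneSet("apc_costimulation", ("CD40", "CD80", "CD86", "ICOSLG", "TNFSF4", "CD70")),
    GeneSet("apc_coinhibition", ("CD274", "PDCD1LG2", "VTCN1", "LGALS9")),
    GeneSet("t_cell_costimulation", ("CD28", "ICOS", "TNFRSF4", "TNFRSF9", "CD27")),
    GeneSet("t_cell_coinhibition", ("PDCD1", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "BTLA")),
    GeneSet("mhc_class_i", ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2")),
    GeneSet("batf3_dc", ("BATF3", "IRF8", "FLT3", "THBD", "CLEC9A")),
    GeneSet("ifng_signaling", ("IFNG", "STAT1", "IDO1", "CXCL11", "GZMB", "CXCL9", "CXCL10")),
    GeneSet("cytolytic_activity", ("GZMA", "PRF1", "GZMH", "GNLY", "CCL5")),
)

#: tumor-type codes: 25 "warm" types plus 6 "cold" low-inflammation types
WARM_TYPES: tuple[str, ...] = (
    "BRCA", "OV", "PAAD", "COAD", "LUAD", "STAD", "CESC", "UCEC", "BLCA",
    "THYM", "HNSC", "KIRC", "LUSC", "MESO", "SKCM", "PRAD", "LIHC", "KIRP",
    "THCA", "ESCA", "SARC", "READ", "TGCT", "CHOL", "LGG",
)
COLD_TYPES: tuple[str, ...] = ("UVM", "ACC", "UCS", "GBM", "PCPG", "KICH")

#: default planted TMB-associated types (ordered)
TMB_ASSOCIATED_TYPES: tuple[str, ...] = (
    "CESC", "STAD", "LUAD", "BRCA", "COAD", "THYM", "UCEC", "BLCA",
)

#: per-type KRAS mutation prevalence (others default to 0.05; MESO has none)
KRAS_PREVALENCE: dict[str, float] = {
    "PAAD": 0.73, "COAD": 0.48, "READ": 0.38, "LUAD": 0.30, "UCEC": 0.18, "MESO": 0.0,
}
KRAS_PREVALENCE_DEFAULT = 0.05

#: frequently mutated genes and their sampling weights
_TOP_MUTATED = {
    "TTN": 0.05, "TP53": 0.04, "MUC16": 0.03, "CSMD3": 0.025, "RYR2": 0.02,
    "LRP1B": 0.02, "SYNE1": 0.015, "USH2A": 0.015, "FLG": 0.01, "PIK3CA": 0.01,
}
_PATHWAY_WEIGHT = 0.002  # MLH1..POLD1: rare
_PATHWAY_GENE_LIST = ("MLH1", "MSH2", "MSH6", "PMS2", "BRCA1", "BRCA2", "PALB2", "POLE", "POLD1")
_N_FILLER_GENES = 150

#: variant-classification sampling distribution (sums to 1)
VARIANT_CLASS_PROBS: dict[str, float] = {
    "Missense_Mutation": 0.55,
    "Silent": 0.20,
    "Nonsense_Mutation": 0.05,
    "Frame_Shift_Del": 0.04,
    "Frame_Shift_Ins": 0.03,
    "Splice_Site": 0.04,
    "In_Frame_Del": 0.02,
    "In_Frame_Ins": 0.01,
    "3'UTR": 0.03,
    "Intron": 0.02,
    "Nonstop_Mutation": 0.005,
    "Translation_Start_Site": 0.005,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a pan-cancer discovery cohort: 31 tumor types of 225
    samples (six of them inflammation-cold), ~3% MSI and ~24% HRD
    subpopulations, a planted treatment hazard ratio of 0.5 for the
    inflammation-high group, and DCB probabilities of 0.36/0.16/0 for the
    hi/med/lo groups.
    """

    n_tumor_types: int = 31
    samples_per_type: int | Sequence[int] = 225
    n_background_genes: int = 200
    inflammation_effect: float = 2.0  # log2 shift of chemokines per unit latent factor
    immune_loading: float = 0.8  # relative loading of immune-geneset genes
    msi_fraction: float = 0.03
    hrd_fraction: float = 0.24
    tmb_base_mean: float = 100.0  # expected mutation records per sample
    tmb_msi_multiplier: float = 10.0
    tmb_association_multiplier: float = 3.0
    n_tmb_associated_types: int = 8
    n_cold_types: int = 6
    cold_type_size_divisor: int = 3  # cold types are rarer entities: size // divisor
    cold_inflammation_mean: float = -4.0  # latent-factor mean of cold types
    type_effect_sd: float = 0.3
    expression_noise_sd: float = 1.0
    msi_cscore_boost: float = 0.5  # extra log2 chemokine expression in MSI samples
    hrd_cscore_boost: float = 0.25
    hazard_ratio_hi: float = 0.5
    ttp_median_ref_days: float = 72.0
    os_median_ref_days: float = 196.0
    dcb_prob_by_group: tuple[float, float, float] = (0.36, 0.16, 0.0)
    censoring_rate: float = 0.3
    missing_score_fraction: float = 0.02
    nb_dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor_types <= 0:
            raise ValueError("n_tumor_types must be positive")
        sizes = self.per_type_sizes()
        if any(s <= 0 for s in sizes):
            raise ValueError("samples_per_type entries must be positive")
        if self.n_background_genes <= 0:
            raise ValueError("n_background_genes must be positive")
        for name in ("msi_fraction", "hrd_fraction", "censoring_rate", "missing_score_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "tmb_base_mean", "tmb_msi_multiplier", "tmb_association_multiplier",
            "hazard_ratio_hi", "ttp_median_ref_days", "os_median_ref_days", "nb_dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.dcb_prob_by_group) != 3 or any(
            not 0.0 <= p <= 1.0 for p in self.dcb_prob_by_group
        ):
            raise ValueError("dcb_prob_by_group must be three probabilities in [0, 1]")
        if not 0 <= self.n_cold_types < self.n_tumor_types:
            raise ValueError("n_cold_types must be in [0, n_tumor_types)")
        if self.n_tmb_associated_types > self.n_tumor_types - self.n_cold_types:
            raise ValueError("cannot plant more TMB-associated types than warm types")

    def per_type_sizes(self) -> list[int]:
        """Per-type sample counts, warm types first then cold.

        With a scalar ``samples_per_type`` the cold (low-inflammation) types
        are generated at ``samples_per_type // cold_type_size_divisor``,
        mirroring the rarity of such entities in real pan-cancer cohorts; an
        explicit list is used as given.
        """
        if isinstance(self.samples_per_type, int):
            if self.cold_type_size_divisor < 1:
                raise ValueError("cold_type_size_divisor must be >= 1")
            warm = self.n_tumor_types - self.n_cold_types
            cold_size = max(5, self.samples_per_type // self.cold_type_size_divisor)
            return [self.samples_per_type] * warm + [cold_size] * self.n_cold_types
        sizes = list(self.samples_per_type)
        if len(sizes) != self.n_tumor_types:
            raise ValueError("samples_per_type list length must equal n_tumor_types")
        return sizes

    def tumor_type_names(self) -> tuple[list[str], list[str]]:
        """(warm, cold) type codes in use."""
        n_warm = self.n_tumor_types - self.n_cold_types
        warm = list(WARM_TYPES[:n_warm])
        warm += [f"WT{i:02d}" for i in range(len(warm), n_warm)]
        cold = list(COLD_TYPES[: self.n_cold_types])
        cold += [f"CT{i:02d}" for i in range(len(cold), self.n_cold_types)]
        return warm, cold

    def tmb_associated_types(self) -> list[str]:
        warm, _ = self.tumor_type_names()
        planted = [t for t in TMB_ASSOCIATED_TYPES if t in warm]
        for t in warm:
            if len(planted) >= self.n_tmb_associated_types:
                break
            if t not in planted:
                planted.append(t)
        return sorted(planted[: self.n_tmb_associated_types])


def _immune_genes() -> list[str]:
    genes: dict[str, None] = {}
    for gs in DEFAULT_GENESETS:
        for g in gs.genes:
            if g not in CHEMOKINES:
                genes.setdefault(g)
    return list(genes)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (expression, mutation table, clinical table) for one cohort.

    Expression is genes-by-samples on the log2(TPM + 0.001) scale; the
    mutation table uses MAF column names; the clinical table carries survival,
    DCB, genomic scores and the planted ground-truth columns (``*_planted``).
    """
    rng = np.random.default_rng(config.seed)
    warm, cold = config.tumor_type_names()
    types = warm + cold
    sizes = config.per_type_sizes()

    tumor_type = np.repeat(types, sizes)
    n = tumor_type.size
    sample_ids = np.array(
        [f"{t}-{i:04d}" for t, i in zip(tumor_type, np.concatenate([np.arange(s) for s in sizes]))]
    )

    # latent inflammation factor: type mean + unit normal per sample
    type_means = {t: m for t, m in zip(warm, rng.normal(0.0, config.type_effect_sd, len(warm)))}
    type_means.update({t: config.cold_inflammation_mean for t in cold})
    z = np.array([type_means[t] for t in tumor_type]) + rng.standard_normal(n)

    msi = rng.random(n) < config.msi_fraction
    hrd = rng.random(n) < config.hrd_fraction

    # --- expression -------------------------------------------------------
    immune = _immune_genes()
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    genes = list(CHEMOKINES) + immune + background
    loading = np.concatenate(
        [
            np.full(len(CHEMOKINES), 1.0),
            np.full(len(immune), config.immune_loading),
            np.zeros(len(background)),
        ]
    )
    baseline = np.concatenate(
        [
            rng.normal(3.0, 0.5, len(CHEMOKINES)),
            rng.normal(3.0, 1.0, len(immune)),
            rng.normal(3.0, 1.0, len(background)),
        ]
    )
    boost = config.msi_cscore_boost * msi + config.hrd_cscore_boost * hrd
    expr = (
        baseline[:, None]
        + loading[:, None] * (config.inflammation_effect * z + boost)[None, :]
        + rng.normal(0.0, config.expression_noise_sd, (len(genes), n))
    )
    # a slice of background genes is zero-inflated to exercise the 50% filter
    n_rare = max(1, config.n_background_genes // 7)
    rare_rows = len(CHEMOKINES) + len(immune) + np.arange(n_rare)
    expr[rare_rows] = np.where(
        rng.random((n_rare, n)) < 0.7, LOG2_FLOOR, expr[rare_rows]
    )
    expr = np.maximum(expr, LOG2_FLOOR)
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    # planted grouping = cohort-relative quartile stratification of the
    # realized chemokine score, so downstream scoring recovers it exactly
    cscore = compute_cscore(expression)
    thresholds = derive_thresholds(cscore)
    group_planted = stratify(cscore, thresholds)["group"].astype(str).to_numpy()
    pooled_hi = pool_groups(pd.Series(group_planted, index=sample_ids)) == "hi"
    pooled_hi = pooled_hi.to_numpy()

    # --- mutations --------------------------------------------------------
    assoc_types = set(config.tmb_associated_types())
    type_mult = {t: m for t, m in zip(types, rng.lognormal(0.0, 0.3, len(types)))}
    mu = config.tmb_base_mean * np.array([type_mult[t] for t in tumor_type])
    mu = mu * np.where(msi, config.tmb_msi_multiplier, 1.0)
    in_assoc = np.isin(tumor_type, list(assoc_types))
    mu = mu * np.where(in_assoc & pooled_hi, config.tmb_association_multiplier, 1.0)
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    gene_pool = list(_TOP_MUTATED) + list(_PATHWAY_GENE_LIST) + [
        f"MUTG{i:03d}" for i in range(_N_FILLER_GENES)
    ]
    weights = np.array(
        list(_TOP_MUTATED.values())
        + [_PATHWAY_WEIGHT] * len(_PATHWAY_GENE_LIST)
        + [0.0] * _N_FILLER_GENES
    )
    weights[len(_TOP_MUTATED) + len(_PATHWAY_GENE_LIST):] = (1.0 - weights.sum()) / _N_FILLER_GENES
    total = int(counts.sum())
    maf = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": np.repeat(sample_ids, counts),
            "Hugo_Symbol": rng.choice(gene_pool, size=total, p=weights),
            "Variant_Classification": rng.choice(
                list(VARIANT_CLASS_PROBS), size=total, p=list(VARIANT_CLASS_PROBS.values())
            ),
        }
    )
    # KRAS mutations planted at per-type prevalence
    kras_p = np.array(
        [KRAS_PREVALENCE.get(t, KRAS_PREVALENCE_DEFAULT) for t in tumor_type]
    )
    kras_mut = rng.random(n) < kras_p
    kras_class = np.where(rng.random(int(kras_mut.sum())) < 0.9, "Missense_Mutation", "Nonsense_Mutation")
    kras_records = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": sample_ids[kras_mut],
            "Hugo_Symbol": "KRAS",
            "Variant_Classification": kras_class,
        }
    )
    maf = pd.concat([maf, kras_records], ignore_index=True)

    # --- genomic scores consistent with planted membership ------------------
    mantis = np.where(msi, rng.uniform(0.45, 0.9, n), rng.uniform(0.05, 0.35, n))
    in_brca_ov = np.isin(tumor_type, ["BRCA", "OV"])
    hrd_score = np.where(
        hrd,
        np.where(in_brca_ov, rng.uniform(46.0, 90.0, n), rng.uniform(27.0, 70.0, n)),
        np.where(in_brca_ov, rng.uniform(0.0, 45.0, n), rng.uniform(0.0, 26.0, n)),
    )
    msisensor = np.where(msi, rng.uniform(0.3, 5.0, n), rng.uniform(0.0, 0.15, n))
    miss_mantis = rng.random(n) < config.missing_score_fraction
    miss_hrd = rng.random(n) < config.missing_score_fraction
    mantis = np.where(miss_mantis, np.nan, mantis)
    hrd_score = np.where(miss_hrd, np.nan, hrd_score)

    # --- survival and clinical benefit --------------------------------------
    lam_ttp = np.log(2.0) / config.ttp_median_ref_days
    lam_os = np.log(2.0) / config.os_median_ref_days
    hr = np.where(pooled_hi, config.hazard_ratio_hi, 1.0)
    ttp_days, ttp_event = _censored_exponential(rng, lam_ttp * hr, lam_ttp, config.censoring_rate, n)
    os_days, os_event = _censored_exponential(rng, lam_os * hr, lam_os, config.censoring_rate, n)

    p_dcb = np.select(
        [group_planted == "hi", group_planted == "med"],
        [config.dcb_prob_by_group[0], config.dcb_prob_by_group[1]],
        default=config.dcb_prob_by_group[2],
    )
    dcb = rng.random(n) < p_dcb
    progressed = np.where(dcb, False, rng.random(n) < 0.5)
    duration = np.where(
        dcb,
        rng.uniform(184.0, 600.0, n),
        np.where(progressed, rng.uniform(10.0, 400.0, n), rng.uniform(10.0, 183.0, n)),
    )

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": sample_ids,
            "tumor_type": tumor_type,
            "ttp_days": ttp_days,
            "ttp_event": ttp_event,
            "os_days": os_days,
            "os_event": os_event,
            "treatment_duration_days": duration,
            "progressed_within_window": progressed.astype(int),
            "dcb": np.where(dcb, "DCB", "NCB"),
            "mantis": mantis,
            "hrd_score": hrd_score,
            "msisensor": msisensor,
            "latent_inflammation": z,
            "msi_planted": msi.astype(int),
            "hrd_planted": hrd.astype(int),
            "group_planted": group_planted,
            "kras_planted": kras_mut.astype(int),
        }
    )
    return expression, maf, clinical


def _censored_exponential(
    rng: np.random.Generator,
    hazard: np.ndarray,
    ref_hazard: float,
    censoring_rate: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with independent exponential censoring.

    The censoring hazard is set so the reference group is censored at roughly
    ``censoring_rate``.
    """
    t = rng.exponential(1.0 / hazard, n)
    if censoring_rate == 0.0:
        return np.maximum(t, 0.5), np.ones(n, dtype=int)
    if censoring_rate >= 1.0:
        c = np.zeros(n)
    else:
        lam_c = ref_hazard * censoring_rate / (1.0 - censoring_rate)
        c = rng.exponential(1.0 / lam_c, n)
    event = (t <= c).astype(int)
    return np.maximum(np.minimum(t, c), 0.5), event


def write_cohort(
    expression: pd.DataFrame,
    maf: pd.DataFrame,
    clinical: pd.DataFrame,
    directory: str | Path,
    genesets: Sequence[GeneSet] = DEFAULT_GENESETS,
) -> dict[str, Path]:
    """Write the three standard inputs plus the GMT so real readers are exercised.

    The expression TSV is written on the log2(TPM + 0.001) scale (the input
    dialect of the discovery data), so write -> read round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "maf": directory / "mutations.maf",
        "clinical": directory / "clinical.tsv",
        "genesets": directory / "genesets.gmt",
    }
    expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    maf.to_csv(paths["maf"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    write_genesets(genesets, paths["genesets"])
    return paths
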