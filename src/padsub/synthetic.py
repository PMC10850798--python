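"""Synthetic multi-dataset LUAD-like cohorts with planted subtype structure.

The generator emulates the statistical skeleton of the real study inputs:
multi-dataset log-scale expression with additive batch offsets, seven
subtypes with distinct up/down pathway activity profiles, clinical
covariates drawn at the published per-subtype frequencies, subtype-shifted
mutational and copy-number burden, subtype-dependent survival and
immunotherapy-response rates, and cross-study drug-sensitivity panels with
planted sensitive (subtype, drug) pairs.  Everything is reproducible from a
single seed, so every downstream stage of the pipeline is testable without
any external download.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

SUBTYPES = ["AD1", "AD2", "AD3", "AD4", "AD5", "AD6", "AD7"]

#: default exome footprint used when emitting synthetic variant tables (Mb)
PANEL_MB = 38.0

# the 50 hallmark pathway names used as the default scoring collection
HALLMARK_PATHWAYS = [
    "HALLMARK_ADIPOGENESIS", "HALLMARK_ALLOGRAFT_REJECTION",
    "HALLMARK_ANDROGEN_RESPONSE", "HALLMARK_ANGIOGENESIS",
    "HALLMARK_APICAL_JUNCTION", "HALLMARK_APICAL_SURFACE",
    "HALLMARK_APOPTOSIS", "HALLMARK_BILE_ACID_METABOLISM",
    "HALLMARK_CHOLESTEROL_HOMEOSTASIS", "HALLMARK_COAGULATION",
    "HALLMARK_COMPLEMENT", "HALLMARK_DNA_REPAIR", "HALLMARK_E2F_TARGETS",
    "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
    "HALLMARK_ESTROGEN_RESPONSE_EARLY", "HALLMARK_ESTROGEN_RESPONSE_LATE",
    "HALLMARK_FATTY_ACID_METABOLISM", "HALLMARK_G2M_CHECKPOINT",
    "HALLMARK_GLYCOLYSIS", "HALLMARK_HEDGEHOG_SIGNALING",
    "HALLMARK_HEME_METABOLISM", "HALLMARK_HYPOXIA",
    "HALLMARK_IL2_STAT5_SIGNALING", "HALLMARK_IL6_JAK_STAT3_SIGNALING",
    "HALLMARK_INFLAMMATORY_RESPONSE", "HALLMARK_INTERFERON_ALPHA_RESPONSE",
    "HALLMARK_INTERFERON_GAMMA_RESPONSE", "HALLMARK_KRAS_SIGNALING_DN",
    "HALLMARK_KRAS_SIGNALING_UP", "HALLMARK_MITOTIC_SPINDLE",
    "HALLMARK_MTORC1_SIGNALING", "HALLMARK_MYC_TARGETS_V1",
    "HALLMARK_MYC_TARGETS_V2", "HALLMARK_MYOGENESIS",
    "HALLMARK_NOTCH_SIGNALING", "HALLMARK_OXIDATIVE_PHOSPHORYLATION",
    "HALLMARK_P53_PATHWAY", "HALLMARK_PANCREAS_BETA_CELLS",
    "HALLMARK_PEROXISOME", "HALLMARK_PI3K_AKT_MTOR_SIGNALING",
    "HALLMARK_PROTEIN_SECRETION",
    "HALLMARK_REACTIVE_OXYGEN_SPECIES_PATHWAY", "HALLMARK_SPERMATOGENESIS",
    "HALLMARK_TGF_BETA_SIGNALING", "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
    "HALLMARK_UNFOLDED_PROTEIN_RESPONSE", "HALLMARK_UV_RESPONSE_DN",
    "HALLMARK_UV_RESPONSE_UP", "HALLMARK_WNT_BETA_CATENIN_SIGNALING",
    "HALLMARK_XENOBIOTIC_METABOLISM",
]

# pathway groups used to translate the qualitative subtype fingerprints
# into concrete hallmark-set lists
_GROUPS = {
    "immune": [
        "HALLMARK_ALLOGRAFT_REJECTION", "HALLMARK_COMPLEMENT",
        "HALLMARK_INFLAMMATORY_RESPONSE", "HALLMARK_IL6_JAK_STAT3_SIGNALING",
        "HALLMARK_INTERFERON_ALPHA_RESPONSE",
        "HALLMARK_INTERFERON_GAMMA_RESPONSE",
    ],
    "cell_cycle": [
        "HALLMARK_E2F_TARGETS", "HALLMARK_G2M_CHECKPOINT",
        "HALLMARK_MITOTIC_SPINDLE", "HALLMARK_MYC_TARGETS_V1",
        "HALLMARK_MYC_TARGETS_V2",
    ],
    "metabolic": [
        "HALLMARK_FATTY_ACID_METABOLISM", "HALLMARK_GLYCOLYSIS",
        "HALLMARK_BILE_ACID_METABOLISM", "HALLMARK_CHOLESTEROL_HOMEOSTASIS",
        "HALLMARK_HEME_METABOLISM", "HALLMARK_XENOBIOTIC_METABOLISM",
        "HALLMARK_PEROXISOME", "HALLMARK_OXIDATIVE_PHOSPHORYLATION",
    ],
    "estrogen": [
        "HALLMARK_ESTROGEN_RESPONSE_EARLY", "HALLMARK_ESTROGEN_RESPONSE_LATE",
    ],
}

# qualitative up/down fingerprint per subtype (the +1/-1 entries of the
# default profile matrix); everything not listed is 0
_FINGERPRINT: dict[str, dict[str, list[str]]] = {
    "AD1": {
        "up": _GROUPS["metabolic"],
        "down": ["HALLMARK_ANGIOGENESIS",
                 "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
                 *_GROUPS["immune"], *_GROUPS["cell_cycle"],
                 "HALLMARK_PI3K_AKT_MTOR_SIGNALING"],
    },
    "AD2": {
        "up": ["HALLMARK_DNA_REPAIR", "HALLMARK_OXIDATIVE_PHOSPHORYLATION",
               *_GROUPS["cell_cycle"]],
        "down": ["HALLMARK_ANGIOGENESIS",
                 "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
                 *_GROUPS["immune"], "HALLMARK_APOPTOSIS",
                 "HALLMARK_TGF_BETA_SIGNALING", "HALLMARK_HEDGEHOG_SIGNALING",
                 "HALLMARK_NOTCH_SIGNALING", "HALLMARK_IL2_STAT5_SIGNALING"],
    },
    "AD3": {
        "up": ["HALLMARK_ANGIOGENESIS",
               "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
               *_GROUPS["immune"], *_GROUPS["metabolic"],
               "HALLMARK_APOPTOSIS", "HALLMARK_HYPOXIA",
               "HALLMARK_PROTEIN_SECRETION", "HALLMARK_P53_PATHWAY",
               "HALLMARK_KRAS_SIGNALING_UP", "HALLMARK_IL2_STAT5_SIGNALING",
               "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
               "HALLMARK_PI3K_AKT_MTOR_SIGNALING",
               "HALLMARK_TGF_BETA_SIGNALING", "HALLMARK_NOTCH_SIGNALING",
               "HALLMARK_MTORC1_SIGNALING"],
        "down": [],
    },
    "AD4": {
        "up": [],
        "down": ["HALLMARK_DNA_REPAIR", *_GROUPS["metabolic"],
                 "HALLMARK_APOPTOSIS", "HALLMARK_HYPOXIA",
                 "HALLMARK_PROTEIN_SECRETION", *_GROUPS["cell_cycle"],
                 "HALLMARK_KRAS_SIGNALING_UP",
                 "HALLMARK_PI3K_AKT_MTOR_SIGNALING",
                 "HALLMARK_TGF_BETA_SIGNALING", "HALLMARK_MTORC1_SIGNALING",
                 "HALLMARK_UNFOLDED_PROTEIN_RESPONSE"],
    },
    "AD5": {
        "up": [*_GROUPS["immune"], "HALLMARK_APOPTOSIS",
               "HALLMARK_P53_PATHWAY", "HALLMARK_IL2_STAT5_SIGNALING",
               "HALLMARK_TNFA_SIGNALING_VIA_NFKB",
               "HALLMARK_HEDGEHOG_SIGNALING"],
        "down": ["HALLMARK_DNA_REPAIR", *_GROUPS["metabolic"],
                 *_GROUPS["cell_cycle"],
                 "HALLMARK_UNFOLDED_PROTEIN_RESPONSE"],
    },
    "AD6": {
        "up": ["HALLMARK_DNA_REPAIR", "HALLMARK_INTERFERON_GAMMA_RESPONSE",
               "HALLMARK_INTERFERON_ALPHA_RESPONSE", *_GROUPS["metabolic"],
               *_GROUPS["cell_cycle"], "HALLMARK_PI3K_AKT_MTOR_SIGNALING",
               "HALLMARK_MTORC1_SIGNALING",
               "HALLMARK_UNFOLDED_PROTEIN_RESPONSE"],
        "down": ["HALLMARK_HEDGEHOG_SIGNALING",
                 "HALLMARK_WNT_BETA_CATENIN_SIGNALING"],
    },
    "AD7": {
        "up": [*_GROUPS["estrogen"], "HALLMARK_NOTCH_SIGNALING"],
        "down": [],
    },
}


def default_profile_matrix() -> pd.DataFrame:
    """Subtype-by-pathway matrix with entries in {+1, 0, -1}."""
    P = pd.DataFrame(0, index=SUBTYPES, columns=HALLMARK_PATHWAYS, dtype=int)
    for subtype, fp in _FINGERPRINT.items():
        P.loc[subtype, fp["up"]] = 1
        P.loc[subtype, fp["down"]] = -1
    return P


# per-subtype clinical frequencies (AD1..AD7 order)
COVARIATE_FREQS: dict[str, list[float]] = {
    "sex_male": [0.5047, 0.5686, 0.5191, 0.4272, 0.4341, 0.5046, 0.4948],
    "stage_late": [0.1339, 0.1958, 0.1900, 0.1493, 0.1450, 0.2047, 0.2118],
    "smoker": [0.6917, 0.8781, 0.7971, 0.7317, 0.7211, 0.8284, 0.7538],
    "egfr_mut": [0.3707, 0.2034, 0.2391, 0.3657, 0.2894, 0.2262, 0.3846],
    "kras_mut": [0.2727, 0.2910, 0.3629, 0.2152, 0.2788, 0.2652, 0.2821],
    "alk_mut": [0.0571, 0.1625, 0.1429, 0.1475, 0.0879, 0.0380, 0.1667],
    "tp53_mut": [0.1409, 0.4970, 0.2169, 0.2500, 0.1407, 0.4366, 0.2632],
    "stk11_mut": [0.2453, 0.2689, 0.0702, 0.0735, 0.0857, 0.0842, 0.0769],
}

# 3-level age-band frequencies (<=50, >50-65, >65) per subtype
AGE_BAND_FREQS = np.array([
    [0.0918, 0.4090, 0.4992],
    [0.1116, 0.4710, 0.4174],
    [0.0862, 0.3864, 0.5274],
    [0.0702, 0.4091, 0.5207],
    [0.0807, 0.3730, 0.5463],
    [0.1013, 0.4502, 0.4485],
    [0.1474, 0.4316, 0.4211],
])

# fraction of samples with the covariate missing, chosen so the
# available-case N of a large cohort resembles the published table
COVARIATE_MISSING = {
    "sex": 0.14, "age": 0.21, "stage": 0.31, "smoking": 0.39,
    "egfr": 0.66, "kras": 0.70, "alk": 0.90, "tp53": 0.81, "stk11": 0.87,
}

# immunotherapy response probability per subtype
RESPONSE_PROBS = [0.152, 0.048, 0.152, 0.344, 0.152, 0.152, 0.152]

# survival log-hazards (better prognosis for AD1/AD4/AD5)
LOG_HAZARDS = [-0.45, 0.15, 0.10, -0.35, -0.30, 0.15, 0.20]

# the 21 immune cell fractions scored by the immune module
IMMUNE_CELL_TYPES = [
    "B_cells", "Plasma_cells", "CD8_T_cells", "CD4_naive_T_cells",
    "T_helper_1", "T_helper_2", "T_helper_17", "T_follicular_helper",
    "T_regulatory", "T_gamma_delta", "T_effector_memory",
    "NK_CD56bright", "NK_CD56dim", "Monocytes", "Macrophages_M1",
    "Macrophages_M2", "Dendritic_active", "Dendritic_resting",
    "Mast_cells", "Eosinophils", "Neutrophils",
]


@dataclass
class SubtypeProfileSpec:
    """Planted subtype structure: labels, pathway profile and mixing.

    ``effect_size`` is the log2-units expression shift applied to member
    genes of a pathway that is up (+) or down (-) in a subtype.
    """

    subtypes: list[str] = field(default_factory=lambda: list(SUBTYPES))
    profile: pd.DataFrame = field(default_factory=default_profile_matrix)
    effect_size: float = 0.5
    proportions: list[float] = field(
        default_factory=lambda: [0.15, 0.18, 0.10, 0.13, 0.21, 0.17, 0.06]
    )
    batch_sd: float = 0.3
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError("mixing proportions must sum to 1")
        if len(self.proportions) != len(self.subtypes):
            raise ValidationError("one mixing proportion per subtype required")
        rows = self.profile.loc[self.subtypes].to_numpy()
        if len({tuple(r) for r in rows}) != len(self.subtypes):
            raise ValidationError("profile rows must be distinct")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    subtype_of: pd.Series
    sensitive_pairs: list[tuple[str, str]]
    log_hazards: dict[str, float]
    response_probs: dict[str, float]

    def __post_init__(self) -> None:
        if self.subtype_of.isna().any():
            raise ValidationError("every sample needs exactly one true subtype")


@dataclass
class SyntheticCohort:
    """Everything :func:`simulate_cohort` produces."""

    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    truth: CohortTruth
    clinical: pd.DataFrame
    variants: pd.DataFrame
    cna: pd.DataFrame
    immune_sets: GeneSetCollection
    marker_genes: dict[str, str]


def _make_gene_sets(
    rng: np.random.Generator, n_genes: int, names: list[str]
) -> dict[str, list[str]]:
    """Sets of 80-150 genes: disjoint 80-gene cores plus extras drawn from a
    shared pool, keeping pairwise overlap far below 10%."""
    core = 80
    need = core * len(names)
    if n_genes < need + 200:
        raise ValidationError(
            f"n_genes={n_genes} too small to host {len(names)} sets "
            f"with disjoint {core}-gene cores"
        )
    genes = [f"G{i:05d}" for i in range(n_genes)]
    pool = genes[need:]
    sets: dict[str, list[str]] = {}
    for i, name in enumerate(names):
        members = genes[i * core:(i + 1) * core]
        extra = int(rng.integers(0, min(70, len(pool)) + 1))
        if extra:
            members = members + list(rng.choice(pool, size=extra, replace=False))
        sets[name] = members
    return sets


def _draw_levels(rng, probs_by_subtype, subtype_idx, levels):
    p = np.asarray(probs_by_subtype)[subtype_idx]
    if p.ndim == 1:  # binary covariate: probability of levels[1]
        return np.where(rng.random(len(subtype_idx)) < p, levels[1], levels[0])
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(subtype_idx))[:, None]
    return np.asarray(levels)[(u > cum).sum(axis=1)]


def simulate_cohort(
    spec: SubtypeProfileSpec | None = None,
    n_datasets: int = 5,
    n_per_dataset: int = 100,
    n_genes: int = 5000,
    seed: int = 0,
    censor_horizon: float = 120.0,
    base_hazard: float = 0.015,
    sensitive_pairs: list[tuple[str, str]] | None = None,
) -> SyntheticCohort:
    """Simulate a multi-dataset cohort with planted subtype structure.

    Expression for gene *g* in sample *j* is
    ``baseline_g + delta * P[subtype(j), pathway(g)] + batch(dataset(j), g)
    + noise`` with batch offsets ~ N(0, 0.3^2) and residual noise ~ N(0, 1).
    Clinical covariates, survival, immunotherapy response, TMB, CNA burden
    and mutational-signature counts are drawn per true subtype.
    """
    spec = spec or SubtypeProfileSpec()
    if n_per_dataset < 10:
        raise ValidationError("n_per_dataset must be >= 10 (dataset-size filter)")
    rng = np.random.default_rng(seed)
    n_subtypes = len(spec.subtypes)
    n_samples = n_datasets * n_per_dataset

    sets = _make_gene_sets(rng, n_genes, list(spec.profile.columns))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    samples = [f"S{j:04d}" for j in range(n_samples)]
    dataset_of = pd.Series(
        [f"DS{j // n_per_dataset + 1}" for j in range(n_samples)], index=samples
    )
    subtype_idx = rng.choice(n_subtypes, size=n_samples, p=spec.proportions)
    subtype_of = pd.Series(
        [spec.subtypes[i] for i in subtype_idx], index=samples, name="subtype"
    )

    # signed pathway effect per gene and sample: sum of delta * P over the
    # sets each gene belongs to
    membership = np.zeros((len(sets), n_genes))
    for row, members in enumerate(sets.values()):
        membership[row, [gene_pos[g] for g in members]] = 1.0
    P = spec.profile.loc[spec.subtypes].to_numpy(dtype=float)  # subtypes x sets
    gene_effect = membership.T @ P.T                           # genes x subtypes
    baseline = rng.normal(7.0, 1.5, size=n_genes)
    batch = rng.normal(0.0, spec.batch_sd, size=(n_datasets, n_genes))
    ds_idx = np.repeat(np.arange(n_datasets), n_per_dataset)
    X = (
        baseline[:, None]
        + spec.effect_size * gene_effect[:, subtype_idx]
        + batch[ds_idx].T
        + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))
    )

    # immune signatures: 21 multi-gene sets from the shared pool, with a
    # planted infiltration profile (AD3/AD5/AD6 hot, AD3 Th2-skewed,
    # AD4 innate-skewed, AD2 immune desert)
    pool = genes[80 * len(sets):]
    immune_sets: dict[str, list[str]] = {}
    taken = 0
    for name in IMMUNE_CELL_TYPES:
        size = int(rng.integers(8, 16))
        immune_sets[name] = pool[taken:taken + size]
        taken += size
    hot = {"AD3": 0.6, "AD5": 0.6, "AD6": 0.4, "AD4": 0.2}
    immune_profile = pd.DataFrame(
        0.0, index=spec.subtypes, columns=IMMUNE_CELL_TYPES
    )
    for s, level in hot.items():
        if s in immune_profile.index:
            immune_profile.loc[s] = level
    if "AD2" in immune_profile.index:
        immune_profile.loc["AD2"] = -0.6
    if "AD3" in immune_profile.index:
        immune_profile.loc["AD3", "T_helper_2"] = 1.2
    if "AD4" in immune_profile.index:
        innate = ["NK_CD56bright", "NK_CD56dim", "Neutrophils", "Eosinophils",
                  "Mast_cells", "T_follicular_helper", "T_helper_17",
                  "T_effector_memory", "T_gamma_delta"]
        immune_profile.loc["AD4", innate] = 0.6
        immune_profile.loc["AD4", ["Macrophages_M2", "T_regulatory"]] = -0.4
    imm_membership = np.zeros((len(IMMUNE_CELL_TYPES), n_genes))
    for row, members in enumerate(immune_sets.values()):
        imm_membership[row, [gene_pos[g] for g in members]] = 1.0
    imm_effect = imm_membership.T @ immune_profile.to_numpy().T
    X += spec.effect_size * imm_effect[:, subtype_idx]

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=samples), dataset_of
    )

    # clinical covariates at the published per-subtype frequencies
    clin = pd.DataFrame(index=samples)
    clin["sample"] = samples
    clin["dataset"] = dataset_of
    band = _draw_levels(rng, AGE_BAND_FREQS, subtype_idx, ["<=50", "50-65", ">65"])
    lo = np.select([band == "<=50", band == "50-65"], [30.0, 50.0], 65.0)
    hi = np.select([band == "<=50", band == "50-65"], [50.0, 65.0], 88.0)
    clin["age"] = np.round(lo + rng.random(n_samples) * (hi - lo), 1)
    clin["sex"] = _draw_levels(rng, COVARIATE_FREQS["sex_male"], subtype_idx, ["F", "M"])
    clin["stage"] = _draw_levels(rng, COVARIATE_FREQS["stage_late"], subtype_idx,
                                 ["early", "late"])
    clin["smoking"] = _draw_levels(rng, COVARIATE_FREQS["smoker"], subtype_idx,
                                   ["never", "ever"])
    for gene_cov in ["egfr", "kras", "alk", "tp53", "stk11"]:
        clin[gene_cov] = _draw_levels(
            rng, COVARIATE_FREQS[f"{gene_cov}_mut"], subtype_idx, ["WT", "MUT"]
        )
    for cov, frac in COVARIATE_MISSING.items():
        mask = rng.random(n_samples) < frac
        clin.loc[mask, cov] = np.nan

    # survival: exponential with subtype log-hazards, uniform censoring
    lh = np.asarray(LOG_HAZARDS[:n_subtypes])
    rate = base_hazard * np.exp(lh[subtype_idx])
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, censor_horizon, size=n_samples)
    clin["os_time"] = np.round(np.minimum(event_time, censor_time), 2)
    clin["os_event"] = (event_time <= censor_time).astype(int)

    # immunotherapy response and a consistent TIDE-like score
    probs = np.asarray(RESPONSE_PROBS[:n_subtypes])
    responder = rng.random(n_samples) < probs[subtype_idx]
    clin["response"] = responder.astype(int)
    clin["tide"] = np.round(
        np.where(responder, rng.normal(-1.0, 0.5, n_samples),
                 rng.normal(1.0, 0.5, n_samples)), 3
    )
    pdl1_mu = np.array([-0.5, -1.0, 1.0, 0.5, 1.0, 1.0, 0.0])[:n_subtypes]
    clin["pdl1_expr"] = np.round(rng.normal(pdl1_mu[subtype_idx], 1.0), 3)
    clin["pd1_expr"] = np.round(rng.normal(0.6 * pdl1_mu[subtype_idx], 1.0), 3)
    ddr_mu = np.where(np.isin(np.array(spec.subtypes)[subtype_idx],
                              ["AD2", "AD6"]), 0.8, 0.0)
    clin["ddr_score"] = np.round(rng.normal(ddr_mu, 1.0), 3)

    # variant table: nonsynonymous counts set the TMB target
    # (lognormal, higher location for AD2/AD6), plus synonymous chaff and
    # mutational-signature attributions
    tmb_mu = np.where(np.isin(np.array(spec.subtypes)[subtype_idx],
                              ["AD2", "AD6"]), 1.1 + 0.7, 1.1)
    tmb = rng.lognormal(tmb_mu, 0.8)
    nonsyn = rng.poisson(tmb * PANEL_MB)
    syn = rng.poisson(0.3 * tmb * PANEL_MB)
    sig_rates = {"SBS1": 2.0, "SBS4": 6.0, "SBS13": 1.0}
    rows = []
    nonsyn_classes = ["Missense_Mutation", "Nonsense_Mutation", "Splice_Site",
                      "Frame_Shift_Del"]
    for j, s in enumerate(samples):
        k = int(nonsyn[j])
        if k:
            eff = rng.choice(nonsyn_classes, size=k, p=[0.7, 0.15, 0.1, 0.05])
            sig = rng.choice(list(sig_rates), size=k,
                             p=np.array(list(sig_rates.values())) / sum(sig_rates.values()))
            gidx = rng.integers(0, n_genes, size=k)
            rows.append(pd.DataFrame({
                "sample": s, "gene": np.array(genes)[gidx],
                "effect": eff, "signature": sig,
            }))
        ks = int(syn[j])
        if ks:
            gidx = rng.integers(0, n_genes, size=ks)
            rows.append(pd.DataFrame({
                "sample": s, "gene": np.array(genes)[gidx],
                "effect": "Silent", "signature": "none",
            }))
    variants = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample", "gene", "effect", "signature"]
    )
    variants["synonymous"] = variants["effect"] == "Silent"
    variants["effect_known"] = True

    # copy-number calls: per-sample altered-gene count ~ negative binomial,
    # higher mean for AD2/AD6
    cna_mean = np.where(np.isin(np.array(spec.subtypes)[subtype_idx],
                                ["AD2", "AD6"]), 600.0, 200.0)
    r = 3.0
    n_alt = rng.negative_binomial(r, r / (r + cna_mean))
    n_alt = np.minimum(n_alt, n_genes)
    cna = np.zeros((n_genes, n_samples), dtype=int)
    for j in range(n_samples):
        if n_alt[j]:
            idx = rng.choice(n_genes, size=int(n_alt[j]), replace=False)
            cna[idx, j] = rng.choice([-2, -1, 1, 2], size=int(n_alt[j]))
    cna_df = pd.DataFrame(cna, index=genes, columns=samples)

    # a handful of immune marker genes (one per signature family)
    marker_genes = {
        "PDL1_like": immune_sets["CD8_T_cells"][0],
        "PD1_like": immune_sets["CD8_T_cells"][1],
        "CTLA4_like": immune_sets["T_regulatory"][0],
        "GZMB_like": immune_sets["NK_CD56dim"][0],
        "LAG3_like": immune_sets["T_helper_1"][0],
    }

    truth = CohortTruth(
        subtype_of=subtype_of,
        sensitive_pairs=sensitive_pairs if sensitive_pairs is not None
        else [("AD2", "DRUG_001"), ("AD4", "DRUG_002")],
        log_hazards=dict(zip(spec.subtypes, lh)),
        response_probs=dict(zip(spec.subtypes, probs)),
    )
    return SyntheticCohort(
        expression=expression,
        gene_sets=GeneSetCollection(sets, category="hallmark"),
        truth=truth,
        clinical=clin,
        variants=variants,
        cna=cna_df,
        immune_sets=GeneSetCollection(immune_sets, category="immune"),
        marker_genes=marker_genes,
    )


def simulate_drug_panel(
    truth: CohortTruth,
    n_lines_per_subtype: int = 3,
    n_drugs: int = 50,
    n_studies: int = 3,
    seed: int = 0,
    shift: float = 0.35,
    missing_frac: float = 0.10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-study cell-line AAC panels with planted sensitive pairs.

    Baseline AAC ~ Beta(2, 8); each planted (subtype, drug) pair receives a
    ``+shift`` mean increase in every study; about ``missing_frac`` of the
    (line, drug, study) entries are missing at random.  Returns the
    long-format panel (study, cell_line, drug, aac) and the cell-line
    subtype labels.
    """
    if n_studies < 2:
        raise ValidationError("need at least 2 studies")
    if n_lines_per_subtype < 2:
        raise ValidationError("need at least 2 cell lines per subtype")
    rng = np.random.default_rng(seed)
    subtypes = sorted(set(truth.subtype_of))
    drugs = [f"DRUG_{i:03d}" for i in range(1, n_drugs + 1)]
    lines, labels = [], []
    for s in subtypes:
        for i in range(n_lines_per_subtype):
            lines.append(f"CL_{s}_{i + 1}")
            labels.append(s)
    labels = pd.Series(labels, index=lines, name="subtype")
    planted = set(truth.sensitive_pairs)
    records = []
    clipped = 0
    for study_i in range(1, n_studies + 1):
        study = f"STUDY{study_i}"
        for line, s in labels.items():
            aac = rng.beta(2.0, 8.0, size=n_drugs)
            for d_i, drug in enumerate(drugs):
                if (s, drug) in planted:
                    aac[d_i] += shift
            if (aac > 1.0).any():
                clipped += int((aac > 1.0).sum())
            aac = np.clip(aac, 0.0, 1.0)
            keep = rng.random(n_drugs) >= missing_frac
            for d_i, drug in enumerate(drugs):
                if keep[d_i]:
                    records.append((study, line, drug, aac[d_i]))
    if clipped:
        warnings.warn(f"{clipped} AAC values clipped to 1.0", stacklevel=2)
    panel = pd.DataFrame(records, columns=["study", "cell_line", "drug", "aac"])
    return panel, labels
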