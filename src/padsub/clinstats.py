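"""Clinical, survival and genomic characterization of consensus subtypes.

Covers covariate association tables (chi-square with an exact/Monte-Carlo
fallback at small expected counts), Cox proportional-hazards overall
survival models adjusted for age, sex, stage, smoking and study, tumor
mutational burden, copy-number burden, mutational-signature positivity,
Kruskal-Wallis group comparisons with Benjamini-Hochberg correction, and
generic cross-tabulation against external subtype labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

logger = logging.getLogger(__name__)

#: common TMB high/low annotation threshold (mutations per Mb)
TMB_HIGH_CUTOFF = 10.0


@dataclass
class AssociationResult:
    """A covariate-by-subtype contingency table with its test."""

    covariate: str
    table: pd.DataFrame          # levels x subtypes counts
    test: str                    # "chi2" | "fisher" | "chi2-monte-carlo"
    statistic: float
    p_value: float
    n: int
    percentages: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.percentages is None:
            col_tot = self.table.sum(axis=0)
            self.percentages = 100.0 * self.table / col_tot.replace(0, np.nan)


def contingency_test(table: pd.DataFrame | np.ndarray,
                     covariate: str = "",
                     exact_seed: int = 0) -> AssociationResult:
    """Pearson chi-square (no continuity correction) on an r x c table.

    When any expected cell count falls below 5 an exact test is used
    instead: Fisher's exact test for 2x2 tables, a Monte-Carlo chi-square
    permutation p-value (fixed seed, 10^4 replicates) for larger tables.
    Levels or subtypes with a zero margin are dropped with a warning.
    """
    tab = pd.DataFrame(table).copy()
    arr = tab.to_numpy()
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency table must hold nonnegative integers")
    zero_rows = tab.index[tab.sum(axis=1) == 0].tolist()
    zero_cols = tab.columns[tab.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        logger.warning("dropping zero-margin levels %s / columns %s",
                       zero_rows, zero_cols)
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValidationError("need >= 2 rows and >= 2 columns with nonzero margins")
    arr = tab.to_numpy().astype(int)
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    test = "chi2"
    if (expected < 5).any():
        if arr.shape == (2, 2):
            test = "fisher"
            _, p = stats.fisher_exact(arr)
        else:
            test = "chi2-monte-carlo"
            rng = np.random.default_rng(exact_seed)
            p = _monte_carlo_chi2_p(arr, chi2, rng)
    return AssociationResult(
        covariate=covariate, table=tab, test=test,
        statistic=float(chi2), p_value=float(p), n=int(arr.sum()),
    )


def _monte_carlo_chi2_p(arr: np.ndarray, observed: float,
                        rng: np.random.Generator, reps: int = 10000) -> float:
    """Permutation p-value for the chi-square statistic with fixed margins."""
    rows = np.repeat(np.arange(arr.shape[0]), arr.sum(axis=1))
    cols = np.repeat(np.arange(arr.shape[1]), arr.sum(axis=0))
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(cols)
        sim = np.zeros_like(arr)
        np.add.at(sim, (rows, perm), 1)
        c, _, _, _ = stats.chi2_contingency(sim + 0, correction=False)
        if c >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


#: default Table-2-style covariates and their level orders
DEFAULT_COVARIATES = {
    "sex": ["M", "F"],
    "age_band": ["<=50", "50-65", ">65"],
    "stage": ["early", "late"],
    "smoking": ["never", "ever"],
    "egfr": ["WT", "MUT"],
    "kras": ["WT", "MUT"],
    "alk": ["WT", "MUT"],
    "tp53": ["WT", "MUT"],
    "stk11": ["WT", "MUT"],
}


def _age_band(age: pd.Series) -> pd.Series:
    return pd.cut(age, bins=[-np.inf, 50, 65, np.inf],
                  labels=["<=50", "50-65", ">65"]).astype(object)


def covariate_table(
    annotations: pd.DataFrame,
    covariates: list[str] | None = None,
    subtype_col: str = "subtype",
) -> list[AssociationResult]:
    """One association test per covariate, on available cases.

    Rows with a missing covariate value are excluded from that covariate's
    table only, so each result carries its own N.  Continuous ``age`` is
    analyzed as the three-level band (<=50, >50-65, >65).
    """
    if subtype_col not in annotations.columns:
        raise ValidationError(f"annotations need a {subtype_col!r} column")
    covariates = covariates or [c for c in DEFAULT_COVARIATES
                                if c.replace("_band", "") in annotations.columns]
    results = []
    for cov in covariates:
        col = cov
        if cov == "age_band":
            series = _age_band(annotations["age"])
        else:
            series = annotations[col]
        mask = series.notna() & annotations[subtype_col].notna()
        if mask.sum() == 0:
            logger.warning("covariate %s entirely missing; skipped", cov)
            continue
        tab = pd.crosstab(series[mask], annotations.loc[mask, subtype_col])
        order = DEFAULT_COVARIATES.get(cov)
        if order:
            tab = tab.reindex([l for l in order if l in tab.index])
        try:
            results.append(contingency_test(tab, covariate=cov))
        except ValidationError as exc:  # e.g. a single observed level
            logger.warning("covariate %s skipped: %s", cov, exc)
    return results


def compute_tmb(
    variants: pd.DataFrame,
    panel_mb: float,
    sequenced_samples: list[str] | None = None,
) -> pd.Series:
    """Nonsynonymous mutations per megabase, per sample.

    Samples absent from the variant table get TMB 0 only when explicitly
    listed in ``sequenced_samples``; otherwise they are simply absent.
    """
    if panel_mb <= 0:
        raise ValidationError("panel_mb must be positive")
    nonsyn = variants.loc[~variants["synonymous"].astype(bool)]
    counts = nonsyn.groupby("sample").size()
    if sequenced_samples is not None:
        counts = counts.reindex(sequenced_samples, fill_value=0)
    return (counts / panel_mb).rename("tmb")


def tmb_high(tmb: pd.Series, cutoff: float = TMB_HIGH_CUTOFF) -> pd.Series:
    """High/low flag at the common 10 mutations/Mb annotation threshold."""
    return (tmb > cutoff).rename("tmb_high")


def cna_burden(cna: pd.DataFrame) -> pd.Series:
    """Number of genes with a non-neutral copy-number call, per sample."""
    arr = cna.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("copy-number calls must be integers")
    return pd.Series((arr != 0).sum(axis=0), index=cna.columns, name="cna_burden")


def signature_positivity(
    attributions: pd.DataFrame,
    subtypes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Positivity flags (>= 1 attributed mutation) and per-subtype percentages.

    ``attributions`` is samples x signatures mutation counts.
    """
    if (attributions.to_numpy() < 0).any():
        raise ValidationError("attribution counts must be nonnegative")
    flags = attributions >= 1
    if subtypes is None:
        return flags, None
    joined = flags.join(subtypes.rename("subtype"), how="inner")
    pct = joined.groupby("subtype").mean() * 100.0
    return flags, pct


@dataclass
class GroupComparison:
    """Omnibus Kruskal-Wallis plus BH-adjusted pairwise rank-sum tests."""

    statistic: float
    p_value: float
    groups: list[str]
    pairwise: pd.DataFrame   # columns: group_a, group_b, statistic, p, p_adj


def group_compare_continuous(
    values: pd.Series, groups: pd.Series
) -> GroupComparison:
    """Kruskal-Wallis over subtypes with BH-adjusted pairwise comparisons.

    Groups with fewer than two non-missing values are dropped with a
    warning.  Pairwise tests are two-sided Mann-Whitney rank-sum tests.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    keep = sizes.index[sizes >= 2].tolist()
    dropped = sizes.index.difference(keep).tolist()
    if dropped:
        logger.warning("dropping groups with < 2 values: %s", dropped)
    df = df[df["group"].isin(keep)]
    if len(keep) < 2:
        raise ValidationError("need >= 2 groups with >= 2 values each")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in keep]
    H, p = stats.kruskal(*samples)
    rows = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            u, pu = stats.mannwhitneyu(samples[i], samples[j],
                                       alternative="two-sided")
            rows.append((keep[i], keep[j], float(u), float(pu)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    else:
        pairwise["p_adj"] = []
    return GroupComparison(statistic=float(H), p_value=float(p),
                           groups=keep, pairwise=pairwise)


@dataclass
class CoxResult:
    """Per-subtype hazard ratios from an adjusted proportional-hazards fit."""

    summary: pd.DataFrame        # index: subtype; HR, CI_low, CI_high, p
    reference: str
    n: int
    n_events: int
    flags: dict[str, str]


def cox_os(
    annotations: pd.DataFrame,
    reference_subtype: str | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "stage", "smoking"),
    subtype_col: str = "subtype",
    pooled_better_vs_worse: bool = False,
) -> CoxResult:
    """Cox OS model: subtype factor + covariates + dataset fixed effect.

    Complete-case rows only; Efron tie handling (the lifelines default).
    The reference subtype defaults to the largest one.  With
    ``pooled_better_vs_worse`` the subtype factor is replaced by a binary
    contrast of {AD1, AD4, AD5} against the rest.
    """
    from lifelines import CoxPHFitter

    needed = [subtype_col, "os_time", "os_event", *covariates]
    if "dataset" in annotations.columns:
        needed.append("dataset")
    df = annotations[needed].dropna().copy()
    if df.empty:
        raise ValidationError("no complete-case rows for the Cox model")
    flags: dict[str, str] = {}
    events_per = df.groupby(subtype_col)["os_event"].sum()
    for s, e in events_per.items():
        if e == 0:
            flags[str(s)] = "no events: HR unstable"
    if pooled_better_vs_worse:
        df["_grp"] = np.where(df[subtype_col].isin(["AD1", "AD4", "AD5"]),
                              "better", "worse")
        factor, reference = "_grp", "better"
    else:
        factor = subtype_col
        reference = reference_subtype or df[subtype_col].value_counts().idxmax()
    design = pd.DataFrame(index=df.index)
    for c in df.columns:
        if c in ("os_time", "os_event", factor, subtype_col) or c == "_grp":
            continue
        if pd.api.types.is_numeric_dtype(df[c]):
            design[c] = df[c].astype(float)
        else:  # categorical adjuster: drop the first level
            levels = sorted(df[c].astype(str).unique())
            for lvl in levels[1:]:
                design[f"{c}_{lvl}"] = (df[c].astype(str) == lvl).astype(float)
    for lvl in sorted(df[factor].astype(str).unique()):
        if lvl != reference:
            design[f"{factor}_{lvl}"] = (df[factor].astype(str) == lvl).astype(float)
    design["os_time"] = df["os_time"].astype(float)
    design["os_event"] = df["os_event"].astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="os_time", event_col="os_event")
    except Exception as exc:  # separation / non-convergence is reported, not hidden
        raise ValidationError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    rows = {}
    np_err = np.seterr(over="ignore")  # flagged no-event levels have huge CIs
    prefix = f"{factor}_"
    for name in summ.index:
        if name.startswith(prefix):
            level = name[len(prefix):]
            rows[level] = {
                "HR": float(np.exp(summ.loc[name, "coef"])),
                "CI_low": float(np.exp(summ.loc[name, "coef lower 95%"])),
                "CI_high": float(np.exp(summ.loc[name, "coef upper 95%"])),
                "p": float(summ.loc[name, "p"]),
            }
    np.seterr(**np_err)
    out = pd.DataFrame(rows).T
    return CoxResult(summary=out, reference=reference, n=len(df),
                     n_events=int(df["os_event"].sum()), flags=flags)


def crosstab_external(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Cross-tabulate two labelings of overlapping samples.

    Returns (contingency table, chi-square p, adjusted Rand index).
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValidationError("no overlapping sample ids")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    tab = pd.crosstab(a, b)
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    ari = adjusted_rand_score(a.to_numpy(), b.to_numpy())
    return tab, float(p), float(ari)
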