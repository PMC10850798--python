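"""Immunotherapy response modeling.

Tests whether the subtype factor adds predictive information for
immunotherapy response beyond PD-L1 expression and TMB, by comparing two
nested binomial GLMs with a likelihood-ratio test, and computes crude
one-vs-rest response odds ratios per subtype with Wald intervals and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GLMFit:
    """A fitted binomial GLM: coefficients, deviance and bookkeeping."""

    params: pd.Series
    deviance: float
    df_model: int
    n: int
    converged: bool
    separation: bool
    predictors: tuple[str, ...]


def median_dichotomize(values: pd.Series) -> pd.Series:
    """High/low split at the median (strictly above = high)."""
    return (values > values.median()).map({True: "high", False: "low"})


def fit_response_glm(
    response: pd.Series,
    predictors: pd.DataFrame,
) -> GLMFit:
    """Logit-link binomial fit of a binary response on a design frame.

    Categorical predictor columns are dummy-coded dropping the first level.
    Non-convergence and (quasi-)separation are reported in the result,
    never silently.
    """
    y = pd.Series(response).dropna()
    if set(pd.unique(y)) - {0, 1}:
        raise ValidationError("response must be binary 0/1")
    if y.nunique() < 2:
        raise ValidationError("response has a single class")
    X = predictors.loc[y.index].copy()
    cat_cols = [c for c in X.columns if not pd.api.types.is_numeric_dtype(X[c])]
    if cat_cols:
        X = pd.get_dummies(X, columns=cat_cols, drop_first=True, dtype=float)
    if X.shape[1] == 0:
        X = pd.DataFrame(index=y.index)
    X = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y.astype(float), X, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    fitted = res.predict(X)
    separation = bool((fitted > 1 - 1e-8).any() or (fitted < 1e-8).any())
    if separation:
        logger.warning("possible separation: fitted probabilities at 0/1")
    return GLMFit(
        params=res.params,
        deviance=float(res.deviance),
        df_model=int(res.df_model),
        n=len(y),
        converged=bool(res.converged),
        separation=separation,
        predictors=tuple(predictors.columns),
    )


def lrt_nested(reduced: GLMFit, full: GLMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested binomial GLMs.

    The statistic is the deviance difference; df is the parameter-count
    difference (6 for a 7-level subtype factor added to the reduced model).
    """
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValidationError("models are not nested (predictor sets)")
    if reduced.n != full.n:
        raise ValidationError("models were fit on different samples")
    statistic = reduced.deviance - full.deviance
    df = full.df_model - reduced.df_model
    if df == 0:
        return max(statistic, 0.0), 0, 1.0
    if statistic < 0:
        # numerically tiny negative differences can occur at convergence
        statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def subtype_adds_information(
    annotations: pd.DataFrame,
    subtype_col: str = "subtype",
    include_pd1: bool = False,
) -> dict:
    """Nested-GLM comparison: (PD-L1 high/low + TMB [+ PD-1]) vs + subtype."""
    needed = ["response", "pdl1_expr", "tmb"]
    if include_pd1:
        needed.append("pd1_expr")
    df = annotations[[subtype_col, *needed]].dropna()
    base = pd.DataFrame({
        "pdl1": median_dichotomize(df["pdl1_expr"]),
        "tmb": df["tmb"].astype(float),
    }, index=df.index)
    if include_pd1:
        base["pd1"] = median_dichotomize(df["pd1_expr"])
    reduced = fit_response_glm(df["response"], base)
    full_X = base.copy()
    full_X["subtype"] = df[subtype_col]
    full = fit_response_glm(df["response"], full_X)
    statistic, dof, p = lrt_nested(reduced, full)
    return {
        "reduced": reduced, "full": full,
        "lrt_statistic": statistic, "lrt_df": dof, "lrt_p": p, "n": len(df),
    }


def one_vs_rest_or(
    subtypes: pd.Series,
    response: pd.Series,
) -> pd.DataFrame:
    """Per-subtype one-vs-rest odds ratio for response.

    OR = (a/b) / (c/d) from the responders/non-responders 2x2 table of the
    subtype against all others pooled; Wald 95% CI on the log scale; BH
    adjustment across subtypes.  A zero cell makes the OR undefined and is
    reported as a flag rather than a number.
    """
    df = pd.DataFrame({"subtype": subtypes, "response": response}).dropna()
    rows = []
    for s in sorted(df["subtype"].unique()):
        in_grp = df["subtype"] == s
        a = int(((df["response"] == 1) & in_grp).sum())
        b = int(((df["response"] == 0) & in_grp).sum())
        c = int(((df["response"] == 1) & ~in_grp).sum())
        d = int(((df["response"] == 0) & ~in_grp).sum())
        undefined = 0 in (a, b, c, d)
        if undefined:
            or_, lo, hi, p = np.nan, np.nan, np.nan, np.nan
        else:
            or_ = (a / b) / (c / d)
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            lo = np.exp(np.log(or_) - 1.96 * se)
            hi = np.exp(np.log(or_) + 1.96 * se)
            z = np.log(or_) / se
            p = 2 * stats.norm.sf(abs(z))
        rows.append({
            "subtype": s, "n": a + b, "responders": a, "OR": or_,
            "CI_low": lo, "CI_high": hi, "p": p, "undefined": undefined,
        })
    out = pd.DataFrame(rows).set_index("subtype")
    defined = out.index[~out["undefined"]]
    out["p_adj"] = np.nan
    if len(defined):
        out.loc[defined, "p_adj"] = multipletests(
            out.loc[defined, "p"], method="fdr_bh"
        )[1]
    return out
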