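"""Immune infiltration scoring and marker positivity.

Scores the 21 immune-cell signatures per sample with the same single-sample
enrichment method used for pathways, calls a sample "enriched" for a cell
fraction when its score strictly exceeds the per-dataset median for that
fraction, and applies the analogous per-dataset median split to individual
immune marker genes (checkpoint inhibitors/activators, effector and
exhaustion markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .gsva import PathwayScoreMatrix, gsva_scores
from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


def immune_scores(
    expr: ExpressionMatrix,
    signatures: GeneSetCollection,
    kernel: str = "gaussian",
) -> PathwayScoreMatrix:
    """Per-dataset enrichment scores for multi-gene immune signatures.

    Single-gene signatures are rejected: the random-walk score degenerates
    for them, so they must be replaced by multi-gene counterparts.
    """
    singletons = [n for n, m in signatures.sets.items() if len(m) < 2]
    if singletons:
        raise ValidationError(
            f"single-gene signatures not supported, replace with multi-gene "
            f"counterparts: {singletons}"
        )
    return gsva_scores(expr, signatures, kernel=kernel, min_set_size=2)


def _median_flags(values: pd.DataFrame, dataset_of: pd.Series,
                  per_dataset: bool) -> pd.DataFrame:
    """Strictly-above-median flags, per dataset (default) or globally."""
    flags = pd.DataFrame(False, index=values.index, columns=values.columns)
    if per_dataset:
        for dataset in dataset_of.unique():
            cols = dataset_of.index[dataset_of == dataset]
            cols = [c for c in cols if c in values.columns]
            block = values[cols]
            med = block.median(axis=1)
            flags[cols] = block.gt(med, axis=0)
    else:
        med = values.median(axis=1)
        flags.loc[:, :] = values.gt(med, axis=0)
    return flags


@dataclass
class EnrichmentSummary:
    """Flags (rows x samples) and per-subtype enrichment percentages."""

    flags: pd.DataFrame
    percentages: pd.DataFrame | None   # subtypes x rows


def enrichment_flags(
    scores: PathwayScoreMatrix | pd.DataFrame,
    dataset_of: pd.Series,
    subtypes: pd.Series | None = None,
    per_dataset: bool = True,
) -> EnrichmentSummary:
    """Call a sample enriched for a cell fraction above the median score.

    The cut-off is the per-dataset median of that fraction's scores (a
    config switch selects global medians); the decision uses a strict
    inequality, so a score exactly at the median is not enriched.
    """
    values = scores.values if isinstance(scores, PathwayScoreMatrix) else scores
    counts = dataset_of.value_counts()
    if (counts < 2).any():
        raise ValidationError("every dataset needs >= 2 samples for a median split")
    flags = _median_flags(values, dataset_of, per_dataset)
    pct = None
    if subtypes is not None:
        joined = flags.T.join(subtypes.rename("subtype"), how="inner")
        pct = joined.groupby("subtype").mean() * 100.0
    return EnrichmentSummary(flags=flags, percentages=pct)


def marker_flags(
    expr: ExpressionMatrix,
    marker_genes: list[str],
    subtypes: pd.Series | None = None,
    per_dataset: bool = True,
) -> EnrichmentSummary:
    """Per-dataset median split on individual marker genes' expression.

    Markers absent from the expression matrix are reported and skipped.
    """
    missing = [g for g in marker_genes if g not in expr.values.index]
    if missing:
        logger.warning("markers absent from expression matrix: %s", missing)
    present = [g for g in marker_genes if g in expr.values.index]
    if not present:
        raise ValidationError("no marker genes present in the expression matrix")
    values = expr.values.loc[present]
    flags = _median_flags(values, expr.dataset_of, per_dataset)
    pct = None
    if subtypes is not None:
        joined = flags.T.join(subtypes.rename("subtype"), how="inner")
        pct = joined.groupby("subtype").mean() * 100.0
    return EnrichmentSummary(flags=flags, percentages=pct)
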