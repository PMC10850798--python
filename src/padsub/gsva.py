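"""Single-sample pathway activity scoring.

A self-contained implementation of the GSVA family of scores: each gene's
expression is converted to a cumulative-density statistic against its own
cross-sample distribution (Gaussian kernel or empirical CDF), genes are
ranked per sample, and a weighted Kolmogorov-Smirnov-like random walk over
the ranked list yields one enrichment score per (gene set, sample) in
[-1, 1].  Scores are relative within a sample population, so the statistic
is always computed within one dataset at a time and never pooled across
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

_GENE_BLOCK = 256     # genes per kernel-CDF block (bounds the n^2 buffer)


@dataclass
class PathwayScoreMatrix:
    """Pathway-by-sample enrichment scores in [-1, 1].

    ``provenance`` records (dataset id, fold id, iteration id) when the
    scores were produced under resampling.
    """

    values: pd.DataFrame
    provenance: tuple | None = None

    @property
    def pathways(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


def expression_statistic(values: np.ndarray, kernel: str = "gaussian") -> np.ndarray:
    """Per-gene cumulative-density statistic of each sample's expression.

    Parameters
    ----------
    values
        genes x samples array from a single sample population (one dataset).
    kernel
        ``"gaussian"``: average of normal CDFs centered at each observation
        with bandwidth sd/4 (genes with zero variance fall back to the
        empirical CDF, with a warning).  ``"ecdf"``: tie-averaged empirical
        CDF, i.e. average rank / n.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a genes x samples array")
    n = X.shape[1]
    if n < 3:
        raise ValidationError(f"need >= 3 samples to estimate the statistic, got {n}")
    if kernel == "ecdf":
        return rankdata(X, axis=1, method="average") / n
    if kernel != "gaussian":
        raise ValueError(f"unknown kernel {kernel!r}")
    sd = X.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d genes with zero variance: falling back to ecdf statistic",
            int(flat.sum()),
        )
    h = np.where(flat, 1.0, sd / 4.0)
    out = np.empty_like(X)
    for lo in range(0, X.shape[0], _GENE_BLOCK):
        block = slice(lo, lo + _GENE_BLOCK)
        diffs = (X[block, :, None] - X[block, None, :]) / h[block, None, None]
        out[block] = ndtr(diffs).mean(axis=2)
    if flat.any():
        out[flat] = rankdata(X[flat], axis=1, method="average") / n
    return out


def _ranks(stat: np.ndarray) -> np.ndarray:
    """Per-sample rank of each gene (1 = largest statistic).

    Exact ties are broken by input gene order (stable sort on -stat).
    """
    order = np.argsort(-stat, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order,
                      np.arange(1, stat.shape[0] + 1)[:, None]
                      .repeat(stat.shape[1], axis=1), axis=0)
    return ranks


def _walk_scores(
    ranks: np.ndarray,
    membership: np.ndarray,
    tau: float,
    mode: str,
) -> np.ndarray:
    """Random-walk enrichment scores for all sets and samples.

    The walk statistic only changes slope at member positions, so each
    set's score is computed from its sorted member ranks alone: with member
    ranks r_1 < ... < r_m, weights w_i = |r_i - N/2|**tau and W their sum,
    the deviation just after member i is v_i = cum_i/W - (r_i - i)/(N - m)
    and just before it v_i - w_i/W; extremes of the full walk occur at those
    points (the walk starts and ends at 0).

    ``ranks`` is genes x samples; ``membership`` is sets x genes boolean.
    """
    n_genes, n_samples = ranks.shape
    set_sizes = membership.sum(axis=1)
    if (set_sizes == 0).any() or (set_sizes >= n_genes).any():
        raise ValidationError("each set needs >= 1 member and >= 1 non-member gene")
    scores = np.empty((membership.shape[0], n_samples))
    for row in range(membership.shape[0]):
        idx = np.flatnonzero(membership[row])
        m = len(idx)
        r = np.sort(ranks[idx, :], axis=0).astype(float)    # m x samples
        w = np.abs(r - n_genes / 2.0) ** tau
        cum = np.cumsum(w, axis=0)
        W = cum[-1]
        zero = W == 0
        if zero.any():
            # all members at the exact middle rank: unweighted steps
            flat = np.arange(1, m + 1, dtype=float)[:, None]
            cum = np.where(zero, flat, cum)
            w = np.where(zero, 1.0, w)
            W = np.where(zero, float(m), W)
        i_idx = np.arange(1, m + 1, dtype=float)[:, None]
        v_after = cum / W - (r - i_idx) / (n_genes - m)
        v_before = v_after - w / W
        if mode == "max_diff":
            pos = np.maximum(v_after.max(axis=0), 0.0)
            neg = np.minimum(v_before.min(axis=0), 0.0)
            scores[row] = pos + neg
        else:  # max_deviation
            # candidates in walk order so |v| ties resolve to the earliest
            # position, matching a sequential scan of the full walk
            cand = np.empty((2 * m, r.shape[1]))
            cand[0::2] = v_before
            cand[1::2] = v_after
            pick = np.abs(cand).argmax(axis=0)
            scores[row] = cand[pick, np.arange(n_samples)]
    return scores


def enrichment_score(
    stat_column: np.ndarray,
    member_flags: np.ndarray,
    tau: float = 1.0,
    mode: str = "max_diff",
) -> float:
    """Enrichment score of one gene set for one sample.

    ``stat_column`` holds the sample's per-gene statistics; ``member_flags``
    marks set membership.  Positive scores mean the members concentrate
    among the top-ranked genes.
    """
    stat = np.asarray(stat_column, dtype=float).reshape(-1, 1)
    memb = np.asarray(member_flags, dtype=bool).reshape(1, -1)
    if mode not in ("max_diff", "max_deviation"):
        raise ValueError(f"unknown score mode {mode!r}")
    return float(_walk_scores(_ranks(stat), memb, tau, mode)[0, 0])


def build_membership(
    sets: GeneSetCollection,
    genes: list[str],
    min_set_size: int = 5,
) -> tuple[list[str], np.ndarray]:
    """Set names and a sets x genes boolean membership matrix after
    intersecting each set with the gene universe."""
    retained = sets.intersect(genes, min_size=min_set_size)
    if not len(retained):
        raise ValidationError("all gene sets dropped after intersection")
    gene_pos = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((len(retained), len(genes)), dtype=bool)
    for row, members in enumerate(retained.sets.values()):
        membership[row, [gene_pos[g] for g in members]] = True
    return list(retained.sets), membership


def score_block(
    values: np.ndarray,
    membership: np.ndarray,
    kernel: str = "gaussian",
    tau: float = 1.0,
    mode: str = "max_diff",
) -> np.ndarray:
    """Scores for one sample population given a precomputed membership."""
    stat = expression_statistic(values, kernel=kernel)
    return _walk_scores(_ranks(stat), membership, tau, mode)


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    kernel: str = "gaussian",
    tau: float = 1.0,
    mode: str = "max_diff",
    min_set_size: int = 5,
    provenance: tuple | None = None,
) -> PathwayScoreMatrix:
    """Pathway-by-sample score matrix, computed independently per dataset.

    Sets are intersected with the expression gene universe and dropped when
    fewer than ``min_set_size`` members survive; if no set survives an error
    is raised.  The computation is deterministic.
    """
    set_names, membership = build_membership(sets, expr.genes,
                                             min_set_size=min_set_size)
    X = expr.values.to_numpy()
    out = np.empty((len(set_names), len(expr.samples)))
    col_pos = {s: i for i, s in enumerate(expr.samples)}
    for dataset in expr.datasets:
        cols = [col_pos[s] for s in expr.dataset_samples(dataset)]
        out[:, cols] = score_block(X[:, cols], membership,
                                   kernel=kernel, tau=tau, mode=mode)
    df = pd.DataFrame(out, index=set_names, columns=expr.samples)
    return PathwayScoreMatrix(df, provenance=provenance)
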