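"""Out-of-sample subtype assignment on the consensus map.

New cohorts are scored with the same fold-resampled pathway-scoring
protocol as the training run, projected onto the reference 2D embedding,
and labelled by the most frequent final label among their nearest reference
samples; the per-iteration assignments are then majority-voted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .discovery import ConsensusModel, assign_majority, iteration_scores, make_folds
from .gsva import PathwayScoreMatrix
from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    """Per-sample vote history, final label and diagnostics."""

    votes: pd.DataFrame           # samples x iterations
    final_labels: pd.Series
    vote_fractions: pd.Series
    tie_flags: pd.Series
    mean_neighbor_distance: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.final_labels,
            "vote_fraction": self.vote_fractions,
            "tie": self.tie_flags.astype(int),
            "mean_neighbor_distance": self.mean_neighbor_distance,
        }).rename_axis("sample")


def project_new(model: ConsensusModel, new_scores) -> np.ndarray:
    """Project new samples' pathway scores onto the reference 2D map.

    ``new_scores`` must cover the model's pathway list; rows are aligned by
    name.  Uses the native out-of-sample transform of the stored embedding.
    """
    values = new_scores.values if isinstance(new_scores, PathwayScoreMatrix) else new_scores
    missing = [p for p in model.pathways if p not in values.index]
    if missing:
        raise ValidationError(f"new scores missing pathway rows: {missing[:10]}")
    aligned = values.loc[model.pathways]
    if aligned.shape[1] == 0:
        return np.empty((0, 2))
    reducer = model.reference_reducer()
    return np.asarray(reducer.transform(aligned.to_numpy().T), dtype=float)


def knn_vote(
    coords: np.ndarray,
    reference_coords: np.ndarray,
    reference_labels: pd.Series | np.ndarray,
    k: int = 51,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Most frequent label among the k Euclidean-nearest reference samples.

    Ties go to the lexicographically smallest label and are flagged.
    Returns (labels, tie flags, mean neighbor distance).
    """
    ref_labels = np.asarray(reference_labels)
    ref = np.asarray(reference_coords, dtype=float)
    if k > len(ref):
        raise ValidationError(f"k={k} exceeds reference size {len(ref)}")
    pts = np.asarray(coords, dtype=float)
    if len(pts) == 0:
        return np.empty(0, dtype=object), np.empty(0, dtype=bool), np.empty(0)
    D = cdist(pts, ref)
    nearest = np.argpartition(D, k - 1, axis=1)[:, :k]
    labels = np.empty(len(pts), dtype=object)
    ties = np.empty(len(pts), dtype=bool)
    mean_d = np.empty(len(pts))
    for i in range(len(pts)):
        neigh = nearest[i]
        mean_d[i] = D[i, neigh].mean()
        vals, counts = np.unique(ref_labels[neigh], return_counts=True)
        top = counts.max()
        winners = sorted(vals[counts == top])
        labels[i] = winners[0]
        ties[i] = len(winners) > 1
    return labels, ties, mean_d


def predict_subtypes(
    model: ConsensusModel,
    new_expr: ExpressionMatrix,
    sets: GeneSetCollection,
    n_iterations: int | None = None,
    k_folds: int | None = None,
    seed: int = 0,
    knn: int | None = None,
) -> PredictionResult:
    """Classify a new cohort into the model's consensus subtypes.

    Per iteration: fold-resampled pathway scoring on the new cohort, native
    out-of-sample projection, k-NN vote against the reference samples'
    final labels; the final label is the majority over iterations.
    """
    config = model.config
    n_iterations = n_iterations if n_iterations is not None else config.n_iterations
    k_folds = k_folds if k_folds is not None else config.k_folds
    knn = knn if knn is not None else config.knn_predict
    smallest = new_expr.dataset_of.value_counts().min()
    if smallest < k_folds:
        warnings.warn(
            f"smallest new dataset has {smallest} samples; reducing folds "
            f"from {k_folds} to {smallest}", stacklevel=2,
        )
        k_folds = int(smallest)
    n_ref = len(model.final_labels)
    if knn > n_ref:
        reduced = n_ref if n_ref % 2 else n_ref - 1
        warnings.warn(
            f"k={knn} exceeds the {n_ref}-sample reference map; using "
            f"k={reduced}", stacklevel=2,
        )
        knn = reduced
    ref_labels = model.final_labels.to_numpy()
    vote_cols = {}
    dist_acc = np.zeros(len(new_expr.samples))
    for it in range(n_iterations):
        folds = make_folds(new_expr.dataset_of, k_folds, seed + it + 1)
        scores = iteration_scores(new_expr, sets, folds, config, iteration=it)
        coords = project_new(model, scores)
        labels, _, mean_d = knn_vote(coords, model.reference_coords, ref_labels, knn)
        vote_cols[it] = labels
        dist_acc += mean_d
    votes = pd.DataFrame(vote_cols, index=new_expr.samples)
    final, frac, tie = assign_majority(votes)
    return PredictionResult(
        votes=votes,
        final_labels=final.loc[new_expr.samples],
        vote_fractions=frac.loc[new_expr.samples],
        tie_flags=tie.loc[new_expr.samples],
        mean_neighbor_distance=pd.Series(
            dist_acc / n_iterations, index=new_expr.samples,
            name="mean_neighbor_distance",
        ),
    )
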