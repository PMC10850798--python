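"""Consensus subtype discovery by iterated resampled scoring.

Each iteration partitions every dataset's samples into k folds, recomputes
pathway scores within each (dataset, fold) sample context, embeds the
pooled score matrix into 2D with UMAP and detects subpopulations with
walktrap community detection on a nearest-neighbor graph.  Subpopulation
centroids accumulated across iterations are themselves embedded and
clustered to define the consensus groups, and each sample is finally
assigned to the consensus group it was mapped to the majority of times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .gsva import PathwayScoreMatrix, gsva_scores
from .io import (ExpressionMatrix, GeneSetCollection, PipelineConfig,
                 ValidationError)

logger = logging.getLogger(__name__)

MIN_FOLD_CELL = 3    # smallest (dataset x fold) cell scored on its own
MIN_CENTROIDS = 10   # consensus stage needs several iterations' worth


def make_folds(dataset_of: pd.Series, k: int, seed: int) -> pd.Series:
    """Randomly partition each dataset's samples into k near-equal folds.

    Fold sizes within a dataset differ by at most one.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    folds = pd.Series(-1, index=dataset_of.index, dtype=int)
    for dataset in dataset_of.unique():
        members = dataset_of.index[dataset_of == dataset].to_numpy()
        if len(members) < k:
            raise ValidationError(
                f"dataset {dataset!r} has {len(members)} samples, fewer than k={k}"
            )
        perm = rng.permutation(len(members))
        folds.loc[members[perm]] = np.arange(len(members)) % k
    return folds


def iteration_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    folds: pd.Series,
    config: PipelineConfig,
    iteration: int | None = None,
) -> PathwayScoreMatrix:
    """Score every sample once, within its (dataset, fold) sample context.

    Fold cells with fewer than three samples are merged into the next fold
    of the same dataset, since the kernel statistic needs a population.
    """
    from .gsva import build_membership, score_block

    k = int(folds.max()) + 1
    set_names, membership = build_membership(
        sets, expr.genes, min_set_size=config.min_set_size
    )
    X = expr.values.to_numpy()
    col_pos = {s: i for i, s in enumerate(expr.samples)}
    out = np.empty((len(set_names), len(expr.samples)))
    for dataset in expr.datasets:
        ds_samples = expr.dataset_samples(dataset)
        ds_folds = folds.loc[ds_samples]
        groups: list[list[str]] = [
            ds_folds.index[ds_folds == f].tolist() for f in range(k)
        ]
        merged: list[list[str]] = []
        carry: list[str] = []
        for grp in groups:
            grp = carry + grp
            if 0 < len(grp) < MIN_FOLD_CELL:
                carry = grp
                continue
            carry = []
            if grp:
                merged.append(grp)
        if carry:  # trailing small cell joins the last scored one
            if merged:
                logger.warning(
                    "dataset %s: merging a %d-sample fold cell into its neighbor",
                    dataset, len(carry),
                )
                merged[-1] = merged[-1] + carry
            else:
                merged.append(carry)
        for grp in merged:
            cols = [col_pos[s] for s in grp]
            out[:, cols] = score_block(
                X[:, cols], membership, kernel=config.gsva_kernel,
                tau=config.gsva_tau, mode=config.gsva_mode,
            )
    full = pd.DataFrame(out, index=set_names, columns=expr.samples)
    return PathwayScoreMatrix(full, provenance=(None, None, iteration))


def embed_2d(
    matrix: pd.DataFrame | np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.3,
    seed: int = 0,
    n_epochs: int | None = 200,
):
    """UMAP-embed a features-x-samples matrix into 2D.

    Returns ``(coords, reducer)`` where coords is samples x 2 and the fitted
    reducer supports out-of-sample projection.  Deterministic given seed.
    200 optimization epochs are ample at cohort sizes of a few hundred to a
    few thousand samples and keep repeated embeddings cheap.
    """
    import umap  # deferred: numba compilation is slow at import time

    X = matrix.to_numpy().T if isinstance(matrix, pd.DataFrame) else np.asarray(matrix).T
    if X.shape[0] <= n_neighbors:
        raise ValidationError(
            f"need more than n_neighbors={n_neighbors} samples, got {X.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, n_components=2,
        metric="euclidean", random_state=seed, n_jobs=1, n_epochs=n_epochs,
    )
    coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=float), reducer


def detect_communities(
    coords: np.ndarray,
    graph_k: int = 15,
    walk_steps: int = 4,
    graph: str = "dense",
    weighting: str = "inverse",
) -> np.ndarray:
    """Walktrap communities on a similarity graph of points (Euclidean).

    The walktrap dendrogram is cut at maximum modularity.  By default the
    graph is dense (all pairs): on point sets with well-separated clusters,
    the max-modularity cut of a sparse k-nearest-neighbor graph fragments
    internally uniform clusters (each cluster becomes its own
    near-disconnected component, which modularity then subdivides), whereas
    on the dense weighted graph the cluster partition is the modularity
    optimum.  ``graph="knn"`` selects the sparse symmetric kNN graph
    (``graph_k`` neighbors), with disconnected components clustered
    independently.

    ``weighting`` sets the edge similarity: ``"inverse"`` is 1/(1+d);
    ``"local-gaussian"`` is the self-tuning kernel
    exp(-d^2 / (sigma_i sigma_j)) with sigma_i the distance from point i to
    its ``graph_k``-th neighbor, which adapts to higher-dimensional spaces
    where raw distances concentrate.
    """
    pts = np.asarray(coords, dtype=float)
    n = pts.shape[0]
    if weighting not in ("inverse", "local-gaussian"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if graph == "dense":
        if n < 2:
            raise ValidationError("need at least 2 points")
        from scipy.spatial.distance import pdist, squareform
        iu = np.triu_indices(n, 1)
        d = pdist(pts)
        if weighting == "inverse":
            weights = 1.0 / (1.0 + d)
        else:
            D = squareform(d)
            k_eff = min(graph_k, n - 1)
            sigma = np.sort(D, axis=1)[:, k_eff]
            sigma = np.where(sigma > 0, sigma, 1.0)
            weights = np.exp(-(D ** 2) / np.outer(sigma, sigma))[iu]
        g = ig.Graph(n=n, edges=list(zip(*iu)),
                     edge_attrs={"weight": weights.tolist()})
        clustering = g.community_walktrap(
            weights="weight", steps=walk_steps
        ).as_clustering()
        return np.asarray(clustering.membership, dtype=int)
    if graph != "knn":
        raise ValueError(f"unknown graph mode {graph!r}")
    if n <= graph_k:
        raise ValidationError(f"need more than graph_k={graph_k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=graph_k + 1).fit(pts)
    dist, idx = nn.kneighbors(pts)
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j_pos in range(1, graph_k + 1):
            j = int(idx[i, j_pos])
            key = (min(i, j), max(i, j))
            edges[key] = 1.0 / (1.0 + float(dist[i, j_pos]))
    g = ig.Graph(n=n, edges=list(edges), edge_attrs={"weight": list(edges.values())})
    labels = np.empty(n, dtype=int)
    components = g.connected_components()
    if len(components) > 1:
        logger.info("kNN graph has %d components; clustering each", len(components))
    offset = 0
    for comp in components:
        sub = g.induced_subgraph(comp)
        if sub.vcount() == 1:
            labels[comp[0]] = offset
            offset += 1
            continue
        dendro = sub.community_walktrap(weights="weight", steps=walk_steps)
        clustering = dendro.as_clustering()
        for v, c in zip(comp, clustering.membership):
            labels[v] = offset + c
        offset += len(clustering)
    return labels


def summarize_centroids(
    scores: pd.DataFrame, labels: np.ndarray
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean pathway-score vector and member count per subpopulation label.

    ``scores`` is pathways x samples; returns (centroids as labels x
    pathways, member counts).
    """
    df = scores.T.copy()
    df["_label"] = np.asarray(labels)
    grouped = df.groupby("_label")
    centroids = grouped.mean()
    counts = grouped.size()
    centroids.index.name = "subpopulation"
    return centroids, counts


@dataclass
class ConsensusModel:
    """The trained consensus classifier.

    Holds every iteration's subpopulation centroids, their consensus
    embedding and group labels, the per-sample vote history with the final
    majority label, and the reference map (full-cohort pathway scores and
    their 2D embedding) used for out-of-sample prediction.
    """

    centroids: pd.DataFrame            # columns: iteration, subpopulation, n_members, pathways...
    centroid_coords: np.ndarray        # centroids x 2 consensus embedding
    centroid_labels: pd.Series         # consensus group per centroid
    n_groups: int
    votes: pd.DataFrame                # samples x iterations of consensus labels
    final_labels: pd.Series
    vote_fractions: pd.Series
    tie_flags: pd.Series
    reference_scores: pd.DataFrame     # pathways x samples (no resampling)
    reference_coords: np.ndarray       # samples x 2
    config: PipelineConfig
    _reference_reducer: object | None = field(default=None, repr=False)

    @property
    def group_names(self) -> list[str]:
        return [f"AD{i + 1}" for i in range(self.n_groups)]

    @property
    def n_subtypes(self) -> int:
        """Number of consensus groups realized as final sample labels.

        A centroid-level group that never wins a sample's majority vote
        (an artifact of subpopulations that merged in a few iterations)
        does not constitute a subtype of the cohort.
        """
        return int(self.final_labels.nunique())

    @property
    def pathways(self) -> list[str]:
        return self.reference_scores.index.tolist()

    def reference_reducer(self):
        """The fitted 2D embedding of the reference samples (refit from the
        stored scores and seed if the model was loaded from disk)."""
        if self._reference_reducer is None:
            _, self._reference_reducer = embed_2d(
                self.reference_scores, n_neighbors=self.config.umap_neighbors,
                min_dist=self.config.umap_min_dist, seed=self.config.base_seed,
            )
        return self._reference_reducer

    # -- persistence (plain-text only) ----------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.centroids.to_csv(out / "centroids.tsv", sep="\t", index=False)
        cent = pd.DataFrame(self.centroid_coords, columns=["x", "y"])
        cent["consensus_label"] = self.centroid_labels.to_numpy()
        cent.to_csv(out / "centroid_map.tsv", sep="\t", index=False)
        self.votes.to_csv(out / "votes.tsv", sep="\t")
        labels = pd.DataFrame({
            "label": self.final_labels,
            "vote_fraction": self.vote_fractions,
            "tie": self.tie_flags.astype(int),
        })
        labels.rename_axis("sample").to_csv(out / "labels.tsv", sep="\t")
        self.reference_scores.to_csv(out / "reference_scores.tsv", sep="\t")
        pd.DataFrame(
            self.reference_coords, columns=["x", "y"],
            index=self.reference_scores.columns,
        ).rename_axis("sample").to_csv(out / "reference_coords.tsv", sep="\t")
        self.config.to_yaml(out / "config.yaml")

    @classmethod
    def load(cls, model_dir: str | Path) -> "ConsensusModel":
        d = Path(model_dir)
        config = PipelineConfig.from_yaml(d / "config.yaml")
        centroids = pd.read_csv(d / "centroids.tsv", sep="\t")
        cent_map = pd.read_csv(d / "centroid_map.tsv", sep="\t")
        votes = pd.read_csv(d / "votes.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(d / "labels.tsv", sep="\t", index_col=0)
        ref_scores = pd.read_csv(d / "reference_scores.tsv", sep="\t", index_col=0)
        ref_coords = pd.read_csv(d / "reference_coords.tsv", sep="\t", index_col=0)
        return cls(
            centroids=centroids,
            centroid_coords=cent_map[["x", "y"]].to_numpy(),
            centroid_labels=cent_map["consensus_label"],
            n_groups=int(cent_map["consensus_label"].str.replace("AD", "").astype(int).max()),
            votes=votes,
            final_labels=labels["label"],
            vote_fractions=labels["vote_fraction"],
            tie_flags=labels["tie"].astype(bool),
            reference_scores=ref_scores,
            reference_coords=ref_coords.to_numpy(),
            config=config,
        )


def consensus_cluster(
    centroid_matrix: pd.DataFrame,
    member_counts: np.ndarray,
    config: PipelineConfig,
) -> tuple[pd.Series, np.ndarray, int]:
    """Embed all iteration centroids and group them into consensus subtypes.

    Consensus groups are named AD1..ADk* in decreasing order of total member
    count.  Raises when fewer than :data:`MIN_CENTROIDS` centroids are
    available or when no structure is found (a single community).
    """
    if len(centroid_matrix) < MIN_CENTROIDS:
        raise ValidationError(
            f"consensus stage needs >= {MIN_CENTROIDS} centroids, "
            f"got {len(centroid_matrix)}"
        )
    if np.allclose(centroid_matrix.to_numpy().var(axis=0), 0.0):
        raise ValidationError(
            "no structure: all centroids are identical"
        )
    coords, _ = embed_2d(
        centroid_matrix.T,
        n_neighbors=min(config.consensus_neighbors, len(centroid_matrix) - 1),
        min_dist=config.umap_min_dist, seed=config.base_seed,
    )
    # communities are detected in the full pathway-score space by default
    # (the 2D consensus map is kept for visualization); the self-tuning
    # kernel keeps the detection scale-free in 50 dimensions
    space = coords if config.consensus_space == "embedding" \
        else centroid_matrix.to_numpy()
    raw = detect_communities(space, graph_k=config.graph_k,
                             walk_steps=config.walk_steps,
                             graph=config.consensus_graph,
                             weighting="local-gaussian")
    n_groups = len(np.unique(raw))
    if n_groups < 2:
        raise ValidationError(
            "no structure: all centroids fall in a single consensus group"
        )
    weights = pd.Series(member_counts).groupby(raw).sum()
    order = weights.sort_values(ascending=False).index.tolist()
    rename = {old: f"AD{rank + 1}" for rank, old in enumerate(order)}
    labels = pd.Series([rename[c] for c in raw], index=centroid_matrix.index)
    return labels, coords, n_groups


def assign_majority(votes: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Final label = mode of each sample's vote vector.

    Ties are broken toward the lexicographically smallest label and flagged.
    Returns (labels, vote fractions, tie flags).
    """
    final, frac, tie = {}, {}, {}
    n_iter = votes.shape[1]
    for sample, row in votes.iterrows():
        counts = row.value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        final[sample] = winners[0]
        frac[sample] = top / n_iter
        tie[sample] = len(winners) > 1
    return (pd.Series(final, name="label"),
            pd.Series(frac, name="vote_fraction"),
            pd.Series(tie, name="tie"))


def discover_subtypes(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    config: PipelineConfig | None = None,
) -> ConsensusModel:
    """Run the full consensus subtype-definition framework.

    Iteration i uses seed ``base_seed + i`` for its folds and embedding, so
    the procedure is fully reproducible from the base seed.
    """
    config = config or PipelineConfig()
    per_iter_labels: list[pd.Series] = []
    centroid_rows: list[pd.DataFrame] = []
    for it in range(config.n_iterations):
        seed_i = config.base_seed + it + 1
        folds = make_folds(expr.dataset_of, config.k_folds, seed_i)
        scores = iteration_scores(expr, sets, folds, config, iteration=it)
        if config.cluster_on_embedding:
            coords, _ = embed_2d(
                scores.values, n_neighbors=config.umap_neighbors,
                min_dist=config.umap_min_dist, seed=seed_i,
            )
            space = coords
        else:
            space = scores.values.to_numpy().T
        labels = detect_communities(space, graph_k=config.graph_k,
                                    walk_steps=config.walk_steps,
                                    graph=config.iteration_graph)
        centroids, counts = summarize_centroids(scores.values, labels)
        block = centroids.reset_index()
        block.insert(0, "iteration", it)
        block.insert(2, "n_members", counts.to_numpy())
        centroid_rows.append(block)
        per_iter_labels.append(pd.Series(labels, index=scores.samples, name=it))
        logger.info("iteration %d: %d subpopulations", it, len(centroids))

    all_centroids = pd.concat(centroid_rows, ignore_index=True)
    pathway_cols = [c for c in all_centroids.columns
                    if c not in ("iteration", "subpopulation", "n_members")]
    cent_labels, cent_coords, n_groups = consensus_cluster(
        all_centroids[pathway_cols], all_centroids["n_members"].to_numpy(), config
    )
    all_centroids = all_centroids.copy()
    all_centroids["consensus_label"] = cent_labels.to_numpy()

    # a sample's vote in iteration i is the consensus label of its
    # iteration-subpopulation centroid
    lookup = {
        (row.iteration, row.subpopulation): row.consensus_label
        for row in all_centroids.itertuples()
    }
    votes = pd.DataFrame({
        it: [lookup[(it, lab)] for lab in lab_series]
        for it, lab_series in enumerate(per_iter_labels)
    }, index=expr.samples)
    final_labels, fractions, ties = assign_majority(votes)
    final_labels = final_labels.loc[expr.samples]

    reference = gsva_scores(
        expr, sets, kernel=config.gsva_kernel, tau=config.gsva_tau,
        mode=config.gsva_mode, min_set_size=config.min_set_size,
    )
    ref_coords, reducer = embed_2d(
        reference.values, n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist, seed=config.base_seed,
    )
    return ConsensusModel(
        centroids=all_centroids,
        centroid_coords=cent_coords,
        centroid_labels=cent_labels,
        n_groups=n_groups,
        votes=votes,
        final_labels=final_labels,
        vote_fractions=fractions.loc[expr.samples],
        tie_flags=ties.loc[expr.samples],
        reference_scores=reference.values,
        reference_coords=ref_coords,
        config=config,
        _reference_reducer=reducer,
    )
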