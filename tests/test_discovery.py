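"""Consensus discovery machinery: folds, embedding, communities, voting."""

import numpy as np
import pandas as pd
import pytest

from padsub import (PipelineConfig, ValidationError, assign_majority,
                    consensus_cluster, detect_communities, embed_2d,
                    gsva_scores, iteration_scores, make_folds,
                    summarize_centroids)


class TestMakeFolds:
    def test_ten_samples_five_folds_of_two(self):
        ds = pd.Series("D", index=[f"s{i}" for i in range(10)])
        folds = make_folds(ds, 5, seed=0)
        assert sorted(folds.value_counts()) == [2, 2, 2, 2, 2]

    def test_twelve_samples_five_folds_sizes(self):
        ds = pd.Series("D", index=[f"s{i}" for i in range(12)])
        folds = make_folds(ds, 5, seed=0)
        assert sorted(folds.value_counts()) == [2, 2, 2, 3, 3]

    def test_partition_is_within_dataset(self):
        ds = pd.Series(["A"] * 10 + ["B"] * 10,
                       index=[f"s{i}" for i in range(20)])
        folds = make_folds(ds, 5, seed=1)
        for d in ("A", "B"):
            sizes = folds[ds == d].value_counts()
            assert sorted(sizes) == [2, 2, 2, 2, 2]

    def test_deterministic_and_seed_sensitive(self):
        ds = pd.Series("D", index=[f"s{i}" for i in range(40)])
        a = make_folds(ds, 5, seed=3)
        b = make_folds(ds, 5, seed=3)
        c = make_folds(ds, 5, seed=4)
        assert a.equals(b)
        assert not a.equals(c)

    def test_dataset_smaller_than_k_named_in_error(self):
        ds = pd.Series(["A"] * 10 + ["B"] * 3,
                       index=[f"s{i}" for i in range(13)])
        with pytest.raises(ValidationError, match="'B'"):
            make_folds(ds, 5, seed=0)


class TestIterationScores:
    def test_single_fold_reproduces_plain_scores(self, tiny_expr, tiny_sets):
        cfg = PipelineConfig()
        folds = pd.Series(0, index=tiny_expr.samples)
        it = iteration_scores(tiny_expr, tiny_sets, folds, cfg)
        plain = gsva_scores(tiny_expr, tiny_sets, min_set_size=cfg.min_set_size)
        pd.testing.assert_frame_equal(it.values, plain.values)

    def test_one_column_per_sample(self, tiny_expr, tiny_sets):
        cfg = PipelineConfig(k_folds=3)
        folds = make_folds(tiny_expr.dataset_of, 3, seed=0)
        it = iteration_scores(tiny_expr, tiny_sets, folds, cfg)
        assert it.samples == tiny_expr.samples

    def test_scores_stable_across_fold_draws(self, small_cohort):
        """Different fold partitions perturb but do not scramble scores."""
        from scipy.stats import spearmanr
        cfg = PipelineConfig()
        expr, sets = small_cohort.expression, small_cohort.gene_sets
        a = iteration_scores(expr, sets, make_folds(expr.dataset_of, 5, 1), cfg)
        b = iteration_scores(expr, sets, make_folds(expr.dataset_of, 5, 2), cfg)
        rhos = [spearmanr(a.values[s], b.values[s]).statistic
                for s in expr.samples[:40]]
        assert np.mean(rhos) > 0.8


class TestEmbed:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 60)))
        a, _ = embed_2d(X, n_neighbors=10, seed=5)
        b, _ = embed_2d(X, n_neighbors=10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_two_blobs_separable_in_2d(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 1, size=(50, 40))
        blob2 = rng.normal(6, 1, size=(50, 40))
        X = pd.DataFrame(np.vstack([blob1, blob2]).T)
        coords, _ = embed_2d(X, n_neighbors=15, seed=0)
        from sklearn.linear_model import LogisticRegression
        y = np.array([0] * 50 + [1] * 50)
        acc = LogisticRegression().fit(coords, y).score(coords, y)
        assert acc == 1.0

    def test_duplicated_points_embed_within_local_neighborhood(self):
        """A duplicated input point lands inside its original's 5-NN radius
        (layout repulsion keeps even duplicates ~min_dist apart, so exact
        coincidence is not the contract)."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(40, 30))
        X = np.vstack([base, base[:3]])
        coords, _ = embed_2d(pd.DataFrame(X.T), n_neighbors=10, seed=0)
        from scipy.spatial.distance import cdist
        base_coords = coords[:40]
        dup_d = np.diag(cdist(coords[40:], base_coords[:3]))
        d_base = cdist(base_coords[:3], base_coords)
        r5 = np.sort(d_base, axis=1)[:, 5]
        assert (dup_d <= r5).all()

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.ones((5, 10)))
        with pytest.raises(ValidationError):
            embed_2d(X, n_neighbors=15)


class TestCommunities:
    @staticmethod
    def _modularity_scan_oracle(pts, steps=4):
        """Brute-force cut selection: scan every walktrap merge level and
        pick the partition with maximum modularity, independently of the
        library's own cut."""
        import igraph as ig
        from scipy.spatial.distance import pdist

        n = len(pts)
        iu = np.triu_indices(n, 1)
        w = (1.0 / (1.0 + pdist(pts))).tolist()
        g = ig.Graph(n=n, edges=list(zip(*iu)), edge_attrs={"weight": w})
        dendro = g.community_walktrap(weights="weight", steps=steps)
        best_q, best = -np.inf, None
        for n_clusters in range(1, n + 1):
            try:
                clustering = dendro.as_clustering(n_clusters)
            except Exception:
                continue
            q = g.modularity(clustering.membership, weights="weight")
            if q > best_q:
                best_q, best = q, clustering.membership
        return np.asarray(best)

    def test_two_separated_blobs_give_two_communities(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.5, size=(14, 2)),
                         rng.normal(20, 0.5, size=(14, 2))])
        labels = detect_communities(pts)
        assert len(np.unique(labels)) == 2
        assert len(set(labels[:14])) == 1 and len(set(labels[14:])) == 1
        oracle = self._modularity_scan_oracle(pts)
        assert len(np.unique(oracle)) == 2

    def test_matches_modularity_scan_on_small_point_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pts = np.vstack([
                rng.normal(0, 1, size=(10, 2)),
                rng.normal(8, 1, size=(10, 2)),
                rng.normal([0, 8], 1, size=(10, 2)),
            ])
            labels = detect_communities(pts)
            oracle = self._modularity_scan_oracle(pts)
            from sklearn.metrics import adjusted_rand_score
            assert adjusted_rand_score(labels, oracle) == pytest.approx(1.0)

    def test_point_order_permutation_preserves_partition(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, size=(15, 2)),
                         rng.normal(10, 1, size=(15, 2))])
        labels = detect_communities(pts)
        perm = rng.permutation(len(pts))
        permuted = detect_communities(pts[perm])
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels[perm], permuted) == pytest.approx(1.0)

    def test_knn_mode_still_available(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.5, size=(20, 2)),
                         rng.normal(30, 0.5, size=(20, 2))])
        labels = detect_communities(pts, graph_k=5, graph="knn")
        assert len(np.unique(labels)) >= 2
        assert len(set(labels[:20]) & set(labels[20:])) == 0


class TestCentroids:
    def test_single_member_cluster_is_the_sample(self):
        scores = pd.DataFrame([[1.0, 5.0], [2.0, 6.0]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        cents, counts = summarize_centroids(scores, np.array([0, 1]))
        np.testing.assert_allclose(cents.loc[1], [5.0, 6.0])
        assert counts[1] == 1

    def test_opposite_vectors_average_to_zero(self):
        scores = pd.DataFrame([[1.0, -1.0], [2.0, -2.0]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        cents, _ = summarize_centroids(scores, np.array([0, 0]))
        np.testing.assert_allclose(cents.loc[0], [0.0, 0.0])

    def test_matches_group_by_mean(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.normal(size=(4, 30)),
                              columns=[f"s{i}" for i in range(30)])
        labels = rng.integers(0, 3, size=30)
        cents, counts = summarize_centroids(scores, labels)
        for lab in np.unique(labels):
            expected = scores.loc[:, labels == lab].mean(axis=1)
            np.testing.assert_allclose(cents.loc[lab], expected)
            assert counts[lab] == (labels == lab).sum()


class TestConsensusCluster:
    def test_too_few_centroids_rejected(self):
        cents = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 50)))
        with pytest.raises(ValidationError, match=">= 10 centroids"):
            consensus_cluster(cents, np.ones(5), PipelineConfig())

    def test_identical_centroids_surface_no_structure(self):
        cents = pd.DataFrame(np.zeros((40, 50)))
        cfg = PipelineConfig(consensus_neighbors=10)
        with pytest.raises(ValidationError, match="no structure"):
            consensus_cluster(cents, np.ones(40), cfg)

    def test_groups_named_by_size_and_stable_under_permutation(self):
        rng = np.random.default_rng(8)
        big = rng.normal(0, 0.3, size=(30, 50))
        small = rng.normal(8, 0.3, size=(12, 50))
        cents = pd.DataFrame(np.vstack([big, small]))
        counts = np.array([10] * 30 + [2] * 12)
        cfg = PipelineConfig(consensus_neighbors=8)
        labels, _, k = consensus_cluster(cents, counts, cfg)
        assert k == 2
        assert set(labels[:30]) == {"AD1"}   # heavier group gets the low rank
        assert set(labels[30:]) == {"AD2"}
        perm = rng.permutation(42)
        labels_p, _, k_p = consensus_cluster(
            cents.iloc[perm].reset_index(drop=True), counts[perm], cfg)
        assert k_p == 2
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels.to_numpy()[perm],
                                   labels_p.to_numpy()) == pytest.approx(1.0)


class TestAssignMajority:
    def test_unanimous_vote(self):
        votes = pd.DataFrame({i: ["AD3"] for i in range(100)}, index=["s"])
        labels, frac, tie = assign_majority(votes)
        assert labels["s"] == "AD3" and frac["s"] == 1.0 and not tie["s"]

    def test_even_split_breaks_to_smallest_with_flag(self):
        votes = pd.DataFrame({i: ["AD2" if i < 50 else "AD1"]
                              for i in range(100)}, index=["s"])
        labels, frac, tie = assign_majority(votes)
        assert labels["s"] == "AD1" and frac["s"] == 0.5 and tie["s"]

    def test_mode_matches_brute_force_count(self):
        rng = np.random.default_rng(9)
        votes = pd.DataFrame(
            rng.choice(["AD1", "AD2", "AD3"], size=(20, 31)),
            index=[f"s{i}" for i in range(20)],
        )
        labels, frac, _ = assign_majority(votes)
        for s in votes.index:
            counts = {}
            for v in votes.loc[s]:
                counts[v] = counts.get(v, 0) + 1
            best = max(sorted(counts), key=lambda k: counts[k])
            assert labels[s] == best
            assert frac[s] == pytest.approx(counts[best] / 31)
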