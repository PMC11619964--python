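import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from moals.io_formats import GeneSetCollection
from moals.pathway_feature_selection import (FuzzyKMeans, enrich_clusters,
                                             fit_fuzzy_kmeans, fuzzy_membership,
                                             rank_genes_by_membership,
                                             select_genes, select_pathway_genes,
                                             standardize_profiles,
                                             update_centroids)
from moals.synthetic_data import (ConfigError, SimulationConfig, generate_cohort,
                                  truth_gmt)


def brute_force_membership(X, V, m):
    """Direct double-loop evaluation of the membership formula."""
    n, c = X.shape[0], V.shape[0]
    U = np.zeros((n, c))
    for i in range(n):
        d = [np.linalg.norm(X[i] - V[j]) for j in range(c)]
        for j in range(c):
            U[i, j] = 1.0 / sum((d[j] / d[k]) ** (2 / (m - 1)) for k in range(c))
    return U


class TestFuzzyMembership:
    def test_single_cluster_memberships_are_one(self, rng):
        U = fuzzy_membership(rng.random((10, 3)), rng.random((1, 3)))
        np.testing.assert_array_equal(U, np.ones((10, 1)))

    def test_hand_evaluated_two_centroids(self):
        # point 0 against centroids 1 and 2: u = (0.8, 0.2)
        U = fuzzy_membership(np.array([[0.0]]), np.array([[1.0], [2.0]]),
                             fuzziness=2.0)
        np.testing.assert_allclose(U[0], [0.8, 0.2], atol=1e-12)

    @pytest.mark.parametrize("m", [1.2, 2.0, 3.5])
    def test_equidistant_point_splits_evenly(self, m):
        U = fuzzy_membership(np.array([[0.0, 0.0]]),
                             np.array([[1.0, 0.0], [-1.0, 0.0]]), fuzziness=m)
        np.testing.assert_allclose(U[0], [0.5, 0.5], atol=1e-12)

    def test_coincident_point_tie_rule(self):
        V = np.array([[0.0], [0.0], [5.0]])
        U = fuzzy_membership(np.array([[0.0]]), V)
        np.testing.assert_allclose(U[0], [0.5, 0.5, 0.0])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            X = rng.normal(size=(5, 2))
            V = rng.normal(size=(3, 2))
            m = float(rng.uniform(1.3, 3.0))
            np.testing.assert_allclose(fuzzy_membership(X, V, m),
                                       brute_force_membership(X, V, m),
                                       atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        U = fuzzy_membership(rng.normal(size=(8, 3)), rng.normal(size=(4, 3)))
        np.testing.assert_allclose(U.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((U >= 0) & (U <= 1))


class TestUpdateCentroids:
    def test_near_crisp_limit_recovers_cluster_means(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)),
                       rng.normal(5, 0.1, size=(20, 2))])
        U = np.zeros((40, 2))
        U[:20, 0] = 1.0
        U[20:, 1] = 1.0
        V = update_centroids(X, U, fuzziness=1.01)
        np.testing.assert_allclose(V[0], X[:20].mean(axis=0), atol=1e-3)
        np.testing.assert_allclose(V[1], X[20:].mean(axis=0), atol=1e-3)

    def test_single_point(self):
        V = update_centroids(np.array([[2.0, 3.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(V, [[2.0, 3.0]])

    def test_symmetric_points_give_midpoint(self):
        X = np.array([[-1.0], [1.0]])
        U = np.full((2, 1), 1.0)
        np.testing.assert_allclose(update_centroids(X, U), [[0.0]])


class TestFitFuzzyKMeans:
    def test_planted_blobs_recovered_exactly(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(20, 2)),
                       rng.normal(8, 0.3, size=(20, 2))])
        truth = [0] * 20 + [1] * 20
        fk = fit_fuzzy_kmeans(X, 2, seed=0)
        assert adjusted_rand_score(truth, fk.labels_) == 1.0
        assert fk.converged_

    def test_partition_stable_across_seeds(self, rng):
        X = np.vstack([rng.normal(0, 0.3, size=(20, 2)),
                       rng.normal(8, 0.3, size=(20, 2))])
        a = fit_fuzzy_kmeans(X, 2, seed=1).labels_
        b = fit_fuzzy_kmeans(X, 2, seed=99).labels_
        assert adjusted_rand_score(a, b) == 1.0

    def test_objective_trace_non_increasing(self, rng):
        X = rng.normal(size=(60, 4))
        fk = fit_fuzzy_kmeans(X, 5, seed=3)
        trace = np.array(fk.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_membership_rows_normalized_after_fit(self, rng):
        fk = fit_fuzzy_kmeans(rng.normal(size=(30, 3)), 4, seed=0)
        np.testing.assert_allclose(fk.membership_.sum(axis=1), 1.0, atol=1e-9)

    def test_infinite_tol_stops_after_one_iteration(self, rng):
        fk = FuzzyKMeans(n_clusters=2, tol=np.inf, random_state=0)
        fk.fit(rng.normal(size=(10, 2)))
        assert fk.n_iter_ == 1 and not fk.converged_

    def test_more_clusters_than_points_rejected(self, rng):
        with pytest.raises(ConfigError):
            fit_fuzzy_kmeans(rng.normal(size=(3, 2)), 5)

    def test_sklearn_get_set_params_round_trip(self):
        fk = FuzzyKMeans(n_clusters=7, fuzziness=1.8)
        clone = FuzzyKMeans(**fk.get_params())
        assert clone.get_params() == fk.get_params()


class TestRankGenes:
    def test_argmax_assignment_and_score(self):
        fk = FuzzyKMeans(n_clusters=2)
        fk.membership_ = np.array([[0.9, 0.1], [0.3, 0.7]])
        fk.labels_ = fk.membership_.argmax(axis=1)
        ranked = rank_genes_by_membership(fk, ["GA", "GB"])
        row = ranked[ranked.gene == "GA"].iloc[0]
        assert (row.cluster, row.score) == (0, 0.9)

    def test_uniform_memberships_rank_lexicographically(self):
        fk = FuzzyKMeans(n_clusters=2)
        fk.membership_ = np.full((3, 2), 0.5)
        fk.labels_ = fk.membership_.argmax(axis=1)
        ranked = rank_genes_by_membership(fk, ["GC", "GA", "GB"])
        assert list(ranked.gene) == ["GA", "GB", "GC"]
        assert np.all(ranked.score == 0.5)


class TestEnrichment:
    def _crisp_clustering(self, labels, c):
        fk = FuzzyKMeans(n_clusters=c)
        fk.labels_ = np.asarray(labels)
        fk.membership_ = np.eye(c)[fk.labels_]
        return fk

    def test_exact_tail_for_perfect_overlap(self):
        genes = [f"G{i}" for i in range(20)]
        fk = self._crisp_clustering([0] * 5 + [1] * 15, 2)
        sets = GeneSetCollection(sets={"S": genes[:5]})
        enr = enrich_clusters(fk, genes, sets, genes)
        p = enr[(enr.cluster == 0)].iloc[0].pvalue
        assert p == pytest.approx(1.0 / comb(20, 5), rel=1e-12)

    def test_disjoint_cluster_has_p_one(self):
        genes = [f"G{i}" for i in range(20)]
        fk = self._crisp_clustering([0] * 5 + [1] * 15, 2)
        sets = GeneSetCollection(sets={"S": genes[5:10]})
        enr = enrich_clusters(fk, genes, sets, genes)
        assert enr[enr.cluster == 0].iloc[0].pvalue == 1.0

    def test_bh_adjustment_matches_hand_computation(self):
        """Joint BH across cluster x set tests agrees with the step-up
        formula applied to the raw p-value column."""
        genes = [f"G{i}" for i in range(30)]
        fk = self._crisp_clustering([i // 10 for i in range(30)], 3)
        sets = GeneSetCollection(sets={"A": genes[:10], "B": genes[10:18]})
        enr = enrich_clusters(fk, genes, sets, genes)
        p = enr.pvalue.to_numpy()
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        np.testing.assert_allclose(enr.qvalue.to_numpy(), adj, atol=1e-12)

    def test_missing_background_gene_rejected(self):
        fk = self._crisp_clustering([0, 0], 1)
        sets = GeneSetCollection(sets={"S": ["G1"]})
        with pytest.raises(ValueError, match="background"):
            enrich_clusters(fk, ["G1", "G2"], sets, ["G1"])


class TestSelectPathwayGenes:
    def _setup(self):
        genes = [f"G{i}" for i in range(40)]
        fk = FuzzyKMeans(n_clusters=2)
        fk.labels_ = np.array([0] * 30 + [1] * 10)
        fk.membership_ = np.eye(2)[fk.labels_]
        sets = GeneSetCollection(sets={"HIT": genes[:30], "MISS": genes[35:]})
        enr = enrich_clusters(fk, genes, sets, genes)
        return genes, fk, enr

    def test_enriched_cluster_genes_returned(self):
        genes, fk, enr = self._setup()
        selected = select_pathway_genes(fk, genes, enr, ["HIT"], fdr_cutoff=0.05)
        assert sorted(selected) == sorted(genes[:30])

    def test_zero_cutoff_selects_nothing(self):
        genes, fk, enr = self._setup()
        assert select_pathway_genes(fk, genes, enr, ["HIT"], fdr_cutoff=0.0) == []

    def test_unknown_target_set_rejected(self):
        genes, fk, enr = self._setup()
        with pytest.raises(ConfigError, match="NOPE"):
            select_pathway_genes(fk, genes, enr, ["NOPE"])


class TestPlantedRecovery:
    @pytest.fixture(scope="class")
    @classmethod
    def cohort(cls):
        cfg = SimulationConfig(n_samples=150, n_cases=110, n_controls=40,
                               n_genes_expression=200, n_genes_burden=20,
                               n_burden_signal_genes=10, seed=4)
        return generate_cohort(cfg)

    def test_planted_block_recovered(self, cohort):
        selected, _, _ = select_genes(cohort.expression, truth_gmt(cohort),
                                      ["BLOCK1"], n_clusters=4, seed=0)
        block1 = {g for g, b in cohort.gene_blocks.items() if b == 1}
        recovered = len(block1 & set(selected)) / len(block1)
        assert recovered >= 0.95

    @pytest.mark.parametrize("c", range(6, 13))
    def test_detection_across_cluster_count_scan(self, cohort, c):
        """At every cluster count in the scanned 6-12 range, the planted
        pathway block lands in at least one enriched cluster."""
        selected, _, _ = select_genes(cohort.expression, truth_gmt(cohort),
                                      ["BLOCK1"], n_clusters=c, seed=0)
        assert len(selected) > 0


class TestStandardizeProfiles:
    def test_rows_are_zero_mean_unit_variance(self, small_cohort):
        X, genes = standardize_profiles(small_cohort.expression)
        assert len(genes) == X.shape[0]
        np.testing.assert_allclose(X.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=1), 1.0, atol=1e-9)
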