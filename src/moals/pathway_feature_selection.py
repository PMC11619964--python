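"""Pathway-level gene selection by fuzzy k-means on expression profiles.

Genes are the clustered observations: each gene's vector is its expression
across samples, standardized per gene to zero mean / unit variance so
Euclidean distance compares profile shape rather than magnitude. Soft
cluster memberships

    u_ij = 1 / sum_k (||x_i - v_j|| / ||x_i - v_k||)^(2/(m-1))

are alternated with fuzzy-weighted centroid updates

    v_j = sum_i u_ij^m x_i / sum_i u_ij^m

until centroids stop moving. Clusters are then tested for enrichment in
target gene sets (one-sided hypergeometric tail against a whole-background
universe, Benjamini-Hochberg corrected), and the genes of every cluster
enriched for a target pathway are pooled as the selected expression
features.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, OmicsBlock
from .synthetic_data import ConfigError


def fuzzy_membership(X: np.ndarray, centroids: np.ndarray, fuzziness: float = 2.0
                     ) -> np.ndarray:
    """Membership degrees of each row of X in each centroid's cluster.

    Rows of the returned matrix sum to 1. A point coincident with one or
    more centroids gets membership 1 split equally among the coincident
    centroids and 0 elsewhere.
    """
    if fuzziness <= 1.0:
        raise ValueError(f"fuzziness must be > 1, got {fuzziness}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(centroids, dtype=float))
    d = np.linalg.norm(X[:, None, :] - V[None, :, :], axis=2)  # n x c
    exponent = 2.0 / (fuzziness - 1.0)
    with np.errstate(divide="ignore"):
        inv = d ** (-exponent)
    U = np.empty_like(d)
    coincident = d == 0.0
    regular = ~coincident.any(axis=1)
    U[regular] = inv[regular] / inv[regular].sum(axis=1, keepdims=True)
    for i in np.flatnonzero(coincident.any(axis=1)):
        U[i] = coincident[i] / coincident[i].sum()
    return U


def update_centroids(X: np.ndarray, U: np.ndarray, fuzziness: float = 2.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Fuzzy-weighted mean update of the centroids.

    A cluster whose weights are all zero is re-seeded from a random data
    point (seeded via ``rng``) and a warning is emitted.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.asarray(U, dtype=float) ** fuzziness
    totals = W.sum(axis=0)
    V = np.zeros((U.shape[1], X.shape[1]))
    dead = totals == 0.0
    live = ~dead
    V[live] = (W[:, live].T @ X) / totals[live, None]
    if dead.any():
        warnings.warn(f"re-seeding {int(dead.sum())} empty cluster(s) from random points")
        rng = rng or np.random.default_rng()
        V[dead] = X[rng.integers(0, X.shape[0], size=int(dead.sum()))]
    return V


def _objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, fuzziness: float) -> float:
    d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    return float(((U ** fuzziness) * d2).sum())


class FuzzyKMeans(ClusterMixin, BaseEstimator):
    """Fuzzy k-means (c-means) clustering.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c. Scans over 6-12 are typical for
        genome-scale expression profiles.
    fuzziness : float
        Fuzziness exponent m > 1; 2.0 is the field-standard default.
    tol : float
        Convergence threshold on the maximum centroid displacement.
    max_iter : int
        Iteration cap.
    random_state : int, RandomState or None
        Seeds the random-distinct-points centroid initialization.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) ndarray
    membership_ : (n_points, n_clusters) ndarray, rows sum to 1
    labels_ : argmax-membership hard assignment
    objective_trace_ : list of the fuzzy objective J per iteration
        (non-increasing)
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, n_clusters: int = 8, fuzziness: float = 2.0,
                 tol: float = 1e-5, max_iter: int = 300,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if n < self.n_clusters:
            raise ConfigError(f"{n} points cannot form {self.n_clusters} clusters")
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(2**31))
        V = X[rng.choice(n, size=self.n_clusters, replace=False)].copy()
        trace: list[float] = []
        converged = False
        it = 0
        U = fuzzy_membership(X, V, self.fuzziness)
        for it in range(1, self.max_iter + 1):
            V_new = update_centroids(X, U, self.fuzziness, rng=rng)
            shift = float(np.abs(V_new - V).max()) if self.n_clusters else 0.0
            V = V_new
            U = fuzzy_membership(X, V, self.fuzziness)
            trace.append(_objective(X, U, V, self.fuzziness))
            if shift < self.tol:
                # an infinite tolerance always stops but never certifies
                # convergence
                converged = bool(np.isfinite(self.tol))
                break
        self.cluster_centers_ = V
        self.membership_ = U
        self.labels_ = U.argmax(axis=1)
        self.objective_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def predict(self, X):
        return fuzzy_membership(X, self.cluster_centers_, self.fuzziness).argmax(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def fit_fuzzy_kmeans(X: np.ndarray, n_clusters: int, fuzziness: float = 2.0,
                     tol: float = 1e-5, max_iter: int = 300,
                     seed: int | None = None) -> FuzzyKMeans:
    """Functional wrapper over the FuzzyKMeans estimator."""
    return FuzzyKMeans(n_clusters=n_clusters, fuzziness=fuzziness, tol=tol,
                       max_iter=max_iter, random_state=seed).fit(X)


def standardize_profiles(block: OmicsBlock) -> tuple[np.ndarray, list[str]]:
    """Genes x samples matrix of per-gene standardized expression profiles."""
    X = block.values.T.astype(float)  # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    return (X - mu) / sd, list(block.features)


def rank_genes_by_membership(clustering: FuzzyKMeans, gene_ids: Sequence[str]
                             ) -> pd.DataFrame:
    """Per-gene cluster assignment and centrality score.

    Assigned cluster is the argmax membership, the score its value; genes
    are sorted by descending score within cluster with a deterministic
    lexicographic tie-break on the gene identifier.
    """
    U = clustering.membership_
    df = pd.DataFrame({
        "gene": list(gene_ids),
        "cluster": U.argmax(axis=1),
        "score": U.max(axis=1),
    })
    return df.sort_values(["cluster", "score", "gene"],
                          ascending=[True, False, True]).reset_index(drop=True)


def enrich_clusters(clustering: FuzzyKMeans, gene_ids: Sequence[str],
                    gene_sets: GeneSetCollection,
                    background: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of each cluster in each gene set.

    For a cluster of size n containing k genes of a set of size K drawn
    from a background universe of N genes, the one-sided p-value is
    P(X >= k) under Hypergeom(N, K, n). BH adjustment is applied jointly
    across all cluster x set tests. Set sizes are counted within the
    background; a set disjoint from the background warns and scores p = 1.
    """
    gene_ids = list(gene_ids)
    bg = set(background)
    missing = set(gene_ids) - bg
    if missing:
        raise ValueError(f"background lacks {len(missing)} clustered genes, e.g. {sorted(missing)[:3]}")
    N = len(bg)
    labels = clustering.labels_
    rows = []
    for c in range(clustering.n_clusters):
        members = {g for g, l in zip(gene_ids, labels) if l == c}
        n = len(members)
        for set_name in gene_sets.names():
            set_genes = set(gene_sets[set_name]) & bg
            K = len(set_genes)
            if K == 0:
                warnings.warn(f"gene set {set_name!r} disjoint from background")
                p = 1.0
                k = 0
            else:
                k = len(members & set_genes)
                p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append({"cluster": c, "set": set_name, "overlap": k,
                         "cluster_size": n, "set_size": K, "background_size": N,
                         "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


def select_pathway_genes(clustering: FuzzyKMeans, gene_ids: Sequence[str],
                         enrichment: pd.DataFrame,
                         target_set_names: Sequence[str],
                         fdr_cutoff: float = 0.05) -> list[str]:
    """Union of genes assigned to clusters enriched for any target set.

    A cluster qualifies when its BH-adjusted p-value for at least one
    target set is strictly below ``fdr_cutoff``. Returns the (possibly
    empty) sorted gene list.
    """
    known = set(enrichment["set"])
    unknown = [s for s in target_set_names if s not in known]
    if unknown:
        raise ConfigError(f"unknown target set name(s): {unknown}")
    hits = enrichment[(enrichment["set"].isin(set(target_set_names)))
                      & (enrichment["qvalue"] < fdr_cutoff)]
    clusters = set(hits["cluster"])
    labels = clustering.labels_
    selected = sorted({g for g, l in zip(gene_ids, labels) if l in clusters})
    return selected


def select_genes(expression: OmicsBlock, gene_sets: GeneSetCollection,
                 target_set_names: Sequence[str], n_clusters: int = 8,
                 fuzziness: float = 2.0, fdr_cutoff: float = 0.05,
                 background: Sequence[str] | None = None,
                 seed: int | None = 0,
                 ) -> tuple[list[str], pd.DataFrame, FuzzyKMeans]:
    """End-to-end gene selection: standardize, cluster, enrich, select."""
    X, gene_ids = standardize_profiles(expression)
    clustering = fit_fuzzy_kmeans(X, n_clusters=n_clusters, fuzziness=fuzziness,
                                  seed=seed)
    bg = list(background) if background is not None else gene_ids
    enrichment = enrich_clusters(clustering, gene_ids, gene_sets, bg)
    genes = select_pathway_genes(clustering, gene_ids, enrichment,
                                 target_set_names, fdr_cutoff)
    return genes, enrichment, clustering
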