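"""Population-structure correction: similarity matrix, classical MDS,
k-medoids clustering, and phenotype residualization.

Systematic allele-frequency differences between subpopulations confound
genotype–phenotype association. The correction used here:

1. pairwise accession similarity s_ik = (1/m) Σ_j 1[x_ij == x_kj], the
   fraction of SNPs with identical dosage calls (equivalently 1 − Hamming/m);
2. classical multidimensional scaling: eigendecomposition of the
   double-centred matrix HSH with H = I_n − (1/n) J J^T, retaining the L
   largest positive eigenvalues; coordinates are eigenvectors scaled by
   sqrt(λ);
3. k-medoids (PAM) clustering of the embedding, the cluster count chosen by
   the elbow (maximum discrete second difference) of within-cluster
   dispersion;
4. phenotype adjustment: residuals of a least-squares fit on cluster
   membership indicators, i.e. per-cluster mean-centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import GenotypeMatrix


@dataclass
class MDSEmbedding:
    """Classical-MDS coordinates (n × L) with the retained positive
    eigenvalues sorted descending."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    medoid_indices: np.ndarray


def similarity_matrix(G) -> np.ndarray:
    """Fraction of SNPs with identical calls for every accession pair.

    Computed as Σ_g (X==g)(X==g)^T / m over g ∈ {0,1,2}, avoiding the n²×m
    comparison tensor. Requires a fully imputed matrix.
    """
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if (X == -1).any() or not np.isin(X, (0, 1, 2)).all():
        raise ValueError("genotypes contain missing values; impute before computing similarity")
    m = X.shape[1]
    S = np.zeros((X.shape[0], X.shape[0]))
    for g in (0, 1, 2):
        M = (X == g).astype(np.float64)
        S += M @ M.T
    S /= m
    # clean up round-off so invariants (symmetry, unit diagonal) hold exactly
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S


def double_center(S: np.ndarray) -> np.ndarray:
    """HSH with H = I − J/n; equals subtracting row and column means and
    adding back the grand mean."""
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    return S - row - col + S.mean()


def mds_embed(S: np.ndarray, L: int | None = None, explained: float = 0.9, max_dims: int = 20) -> MDSEmbedding:
    """Classical MDS of a similarity matrix via eigendecomposition of HSH.

    Parameters
    ----------
    S : symmetric n×n similarity matrix with unit diagonal.
    L : number of dimensions to retain; if None, the smallest number of
        positive eigenvalues explaining ≥ ``explained`` of the positive
        eigenvalue mass, capped at ``max_dims``.

    Only positive eigenvalues are ever retained (L is truncated if fewer
    exist); the all-ones direction is annihilated by H and never appears.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    B = double_center(S)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    if not positive.any():
        raise ValueError("similarity matrix is degenerate: no positive eigenvalues after centering")
    n_pos = int(positive.sum())
    if L is None:
        mass = np.cumsum(eigvals[:n_pos]) / eigvals[:n_pos].sum()
        L = int(np.searchsorted(mass, explained) + 1)
        L = min(L, max_dims)
    if L < 1:
        raise ValueError("L must be ≥ 1")
    L = min(L, n_pos, n - 1)
    lam = eigvals[:L]
    coords = eigvecs[:, :L] * np.sqrt(lam)
    return MDSEmbedding(coords, lam)


class KMedoids:
    """Deterministic PAM-style k-medoids on squared Euclidean dissimilarity.

    BUILD: greedy seeding — the first medoid minimizes total dissimilarity,
    each subsequent medoid maximizes the decrease in total cost. SWAP:
    exhaustive medoid/non-medoid exchanges until no swap lowers the cost.
    Ties break toward the lowest index, so the algorithm is deterministic
    without any randomness.
    """

    def __init__(self, n_clusters: int):
        self.n_clusters = n_clusters

    def fit(self, X: np.ndarray) -> "KMedoids":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds sample count {n}")
        sq = (X ** 2).sum(axis=1)
        D = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)

        # BUILD
        medoids = [int(np.argmin(D.sum(axis=1)))]
        dist_to_medoid = D[medoids[0]].copy()
        while len(medoids) < k:
            gains = np.maximum(dist_to_medoid[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            new = int(np.argmax(gains))
            medoids.append(new)
            dist_to_medoid = np.minimum(dist_to_medoid, D[new])

        # SWAP
        medoids = np.array(sorted(medoids))
        best_cost = D[medoids].min(axis=0).sum()
        improved = True
        while improved:
            improved = False
            for mi in range(k):
                for h in range(n):
                    if h in medoids:
                        continue
                    trial = medoids.copy()
                    trial[mi] = h
                    cost = D[trial].min(axis=0).sum()
                    if cost < best_cost - 1e-12:
                        best_cost = cost
                        medoids = np.sort(trial)
                        improved = True
        self.medoid_indices_ = medoids
        self.labels_ = np.argmin(D[medoids], axis=0)
        self.inertia_ = float(best_cost)
        return self


def _within_dispersion(X: np.ndarray, labels: np.ndarray, medoids: np.ndarray) -> float:
    diff = X - X[medoids][labels]
    return float((diff ** 2).sum())


def cluster_accessions(embedding, c_max: int = 10) -> ClusterAssignment:
    """Cluster MDS coordinates with k-medoids for c = 1 … c_max and pick c by
    the elbow rule on within-cluster dispersion.

    The chosen c maximizes the discrete second difference
    W(c−1) − 2W(c) + W(c+1); if the dispersion is already ~0 at c = 1
    (identical points) c = 1 is returned.
    """
    X = embedding.coordinates if isinstance(embedding, MDSEmbedding) else np.asarray(embedding)
    n = X.shape[0]
    if c_max < 2:
        raise ValueError("c_max must be ≥ 2")
    if n < c_max:
        raise ValueError(f"need at least c_max={c_max} points, got {n}")
    fits = {}
    W = []
    for c in range(1, c_max + 1):
        km = KMedoids(c).fit(X)
        fits[c] = km
        W.append(km.inertia_)
    W = np.asarray(W)
    scale = W[0] if W[0] > 0 else 1.0
    if W[0] <= 1e-12:
        c_best = 1
    else:
        # second differences exist for c = 2 … c_max−1
        d2 = W[:-2] - 2 * W[1:-1] + W[2:]
        c_best = int(np.argmax(d2)) + 2
        if d2.max() <= 1e-12 * scale:
            c_best = 1  # dispersion curve has no elbow (e.g. linear decay)
    km = fits[c_best]
    return ClusterAssignment(km.labels_, c_best, km.medoid_indices_)


def adjust_phenotype(y: np.ndarray, clusters: ClusterAssignment | np.ndarray) -> np.ndarray:
    """Residuals of the least-squares fit of y on cluster-membership
    indicators — identical to centering y within each cluster.

    A single-member cluster yields a residual of exactly 0 (warned, since
    that accession carries no information after adjustment).
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else np.asarray(clusters)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != labels.shape[0]:
        raise ValueError("phenotype vector and cluster labels differ in length")
    out = np.empty_like(y)
    for lab in np.unique(labels):
        mask = labels == lab
        if mask.sum() == 1:
            warnings.warn(f"cluster {lab} has a single member; its residual is 0", stacklevel=2)
        out[mask] = y[mask] - y[mask].mean()
    return out


class PopulationStructure(BaseEstimator):
    """Estimator bundling the correction pipeline: similarity → MDS →
    k-medoids → per-cluster residualization.

    Parameters
    ----------
    n_dims : MDS dimensions to retain (None = positive eigenvalues covering
        ≥ 90% of positive mass, capped at 20).
    c_max : largest cluster count tried by the elbow search.

    Attributes (after ``fit``)
    --------------------------
    similarity_ : n×n similarity matrix.
    embedding_ : :class:`MDSEmbedding`.
    clusters_ : :class:`ClusterAssignment`.
    labels_ : cluster label per accession.
    """

    def __init__(self, n_dims: int | None = None, c_max: int = 10):
        self.n_dims = n_dims
        self.c_max = c_max

    def fit(self, G, y=None) -> "PopulationStructure":
        self.similarity_ = similarity_matrix(G)
        self.embedding_ = mds_embed(self.similarity_, L=self.n_dims)
        self.clusters_ = cluster_accessions(self.embedding_, c_max=self.c_max)
        self.labels_ = self.clusters_.labels
        return self

    def adjust(self, y: np.ndarray, environments=None, accessions=None) -> np.ndarray:
        """Residualize a phenotype vector on the fitted cluster structure.

        ``y`` may hold one record per (accession, environment) pair;
        ``accessions`` then gives the accession row index for each record
        (default: ``y`` is ordered like the fitted genotype matrix). If
        ``environments`` is given, adjustment runs separately within each
        environment so that structure is not confounded with climate.
        """
        if not hasattr(self, "clusters_"):
            raise RuntimeError("PopulationStructure must be fitted before adjust()")
        y = np.asarray(y, dtype=float)
        if accessions is None:
            accessions = np.arange(y.shape[0])
        labels = self.labels_[np.asarray(accessions)]
        if environments is None:
            return adjust_phenotype(y, labels)
        environments = np.asarray(environments)
        out = np.empty_like(y)
        for env in np.unique(environments):
            mask = environments == env
            out[mask] = adjust_phenotype(y[mask], labels[mask])
        return out

    def fit_adjust(self, G, y, environments=None, accessions=None) -> np.ndarray:
        return self.fit(G).adjust(y, environments, accessions)
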