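"""Discriminant analysis of principal components (DAPC).

Pipeline: mean-imputed, column-centered PCA of the dosage matrix; k-means
cluster search over a K grid scored by BIC (``n ln(WSS/n) + K ln(n)``); then
linear discriminant assignment with Gaussian class-conditional posteriors
under a shared within-group covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .snp import MISSING, SnpMatrix

_WSS_FLOOR = 1e-12


@dataclass
class PcaModel:
    """Centered PCA of the imputed dosage matrix."""

    means: np.ndarray        # per-site column means used for centering/imputation
    loadings: np.ndarray     # (L, n_axes) orthonormal axes
    scores: np.ndarray       # (n, n_axes) individual scores
    eigenvalues: np.ndarray  # non-increasing

    def project(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) @ self.loadings

    def variance_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def n_axes_for_variance(self, fraction: float = 0.9) -> int:
        """Smallest number of leading axes explaining >= ``fraction`` variance."""
        cum = np.cumsum(self.variance_explained())
        return int(np.searchsorted(cum, fraction - 1e-12) + 1)


@dataclass
class ClusterSearch:
    """k-means search over K with BIC selection."""

    table: pd.DataFrame            # index K; columns WSS, BIC
    assignments: dict[int, np.ndarray]
    optimal_K: int

    def best_assignment(self) -> np.ndarray:
        return self.assignments[self.optimal_K]

    def summary(self) -> str:
        return (
            f"k-means cluster search: optimal K = {self.optimal_K} (min BIC)\n"
            + self.table.to_string(float_format=lambda v: f"{v:.3f}")
        )


@dataclass
class DapcResult:
    """Fitted discriminant model with per-individual posteriors."""

    n_pcs: int
    discriminant_axes: np.ndarray   # (n_pcs, n_da)
    group_means: np.ndarray         # (G, n_pcs)
    groups: np.ndarray              # group codes, sorted
    posteriors: np.ndarray          # (n, G), rows sum to 1
    assignments: np.ndarray         # argmax posterior, as group codes

    def summary(self) -> str:
        acc = {}
        for g in self.groups:
            acc[g] = int((self.assignments == g).sum())
        sizes = "  ".join(f"{g}:{c}" for g, c in acc.items())
        return (
            f"DAPC: {len(self.groups)} groups, {self.n_pcs} retained PCs, "
            f"{self.discriminant_axes.shape[1]} discriminant axes\n"
            f"  assigned sizes: {sizes}\n"
            f"  min posterior max: {self.posteriors.max(axis=1).min():.4f}"
        )


def impute_dosage(m: SnpMatrix) -> np.ndarray:
    """Dosage matrix with missing calls replaced by per-site means."""
    X = m.calls.astype(float)
    X[m.calls == MISSING] = np.nan
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X


def run_pca(m: SnpMatrix | np.ndarray, n_axes: int | None = None) -> PcaModel:
    """PCA of the mean-imputed, column-centered dosage matrix (no scaling)."""
    X = impute_dosage(m) if isinstance(m, SnpMatrix) else np.asarray(m, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 individuals")
    means = X.mean(axis=0)
    Xc = X - means
    # thin SVD: eigenvalues of (1/n) Xc' Xc are s^2 / n
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / n
    if n_axes is None:
        n_axes = int((s > 1e-10).sum())
    n_axes = min(n_axes, len(s))
    return PcaModel(
        means=means,
        loadings=Vt[:n_axes].T,
        scores=Xc @ Vt[:n_axes].T,
        eigenvalues=eig[:n_axes],
    )


def n_pcs_for_clustering(n_individuals: int) -> int:
    """Retained-PC rule of thumb for the cluster search: n/3, at least 1.

    Retaining about a third of the individuals' worth of PCs keeps all the
    group structure while leaving enough isotropic noise dimensions to
    stabilise the WSS/BIC curve against over-splitting.
    """
    return max(1, n_individuals // 3)


def wss(points: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to cluster centroids."""
    total = 0.0
    for g in np.unique(labels):
        sub = points[labels == g]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(total)


def kmeans_bic(n: int, wss_value: float, K: int) -> float:
    """``n ln(WSS/n) + K ln(n)`` with an epsilon floor on WSS."""
    return n * np.log(max(wss_value, _WSS_FLOOR) / n) + K * np.log(n)


def find_clusters(
    scores: np.ndarray,
    K_max: int,
    n_start: int = 500,
    seed: int = 0,
) -> ClusterSearch:
    """Best-of-``n_start`` k-means at each K in 1..K_max, selected by BIC."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n == 0:
        raise ValueError("empty score matrix")
    if K_max > n:
        raise ValueError("K_max exceeds number of individuals")

    rows = []
    assignments: dict[int, np.ndarray] = {}
    for K in range(1, K_max + 1):
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=K,
                n_init=n_start,
                init="k-means++",
                random_state=seed + K,
            ).fit(scores)
            labels = km.labels_
            if len(np.unique(labels)) < K:
                # empty cluster in the best solution: retry a fresh stream
                km = KMeans(
                    n_clusters=K, n_init=n_start, init="k-means++", random_state=seed + K + 7919
                ).fit(scores)
                labels = km.labels_
                if len(np.unique(labels)) < K:
                    continue  # drop this K
        w = wss(scores, labels)
        rows.append((K, w, kmeans_bic(n, w, K)))
        assignments[K] = labels

    table = pd.DataFrame(rows, columns=["K", "WSS", "BIC"]).set_index("K")
    optimal = int(table["BIC"].idxmin())
    return ClusterSearch(table=table, assignments=assignments, optimal_K=optimal)


def fit_assign(
    scores: np.ndarray,
    labels: np.ndarray,
    n_pcs: int | None = None,
    n_da: int | None = None,
    ridge: float = 1e-8,
) -> DapcResult:
    """Linear discriminant assignment of individuals to labeled groups.

    Discriminant axes come from the between/within scatter of the retained
    PCs; posteriors are Gaussian class-conditional densities with the shared
    within-group covariance and uniform group priors.  A ridge is added if
    the within-scatter is singular.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    if n_pcs is None:
        n_pcs = scores.shape[1]
    X = scores[:, :n_pcs]
    n, d = X.shape
    G = len(groups)

    means = np.stack([X[labels == g].mean(axis=0) for g in groups])
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for gi, g in enumerate(groups):
        sub = X[labels == g] - means[gi]
        Sw += sub.T @ sub
        diff = (means[gi] - grand)[:, None]
        Sb += (labels == g).sum() * (diff @ diff.T)
    Sw /= n - G
    if np.linalg.matrix_rank(Sw) < d:
        Sw = Sw + ridge * np.eye(d)

    # discriminant axes: leading eigenvectors of Sw^-1 Sb
    evals, evecs = np.linalg.eig(np.linalg.solve(Sw, Sb))
    order = np.argsort(-evals.real)
    max_da = min(G - 1, d)
    if n_da is None:
        n_da = max_da
    axes = evecs[:, order[: min(n_da, max_da)]].real

    # posteriors: shared-covariance Gaussian densities, uniform priors
    Sw_inv = np.linalg.inv(Sw)
    log_dens = np.empty((n, G))
    for gi in range(G):
        diff = X - means[gi]
        log_dens[:, gi] = -0.5 * np.einsum("ij,jk,ik->i", diff, Sw_inv, diff)
    log_dens -= log_dens.max(axis=1, keepdims=True)
    post = np.exp(log_dens)
    post /= post.sum(axis=1, keepdims=True)

    return DapcResult(
        n_pcs=n_pcs,
        discriminant_axes=axes,
        group_means=means,
        groups=groups,
        posteriors=post,
        assignments=groups[np.argmax(post, axis=1)],
    )
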