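"""Spatial PCA over a collection-site connectivity network, plus geographic
utilities: haversine distance, minimum-spanning connectivity, 25-km thinning,
and admixture-geography correlation.

Spatial PCA finds axes of the site x locus allele-frequency matrix whose
eigenvalue is the product of score variance and a Moran-type spatial
autocorrelation over the connectivity graph, so leading positive axes capture
smooth geographic clines in allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .snp import IndividualMeta, SiteFreqMatrix

EARTH_RADIUS_KM = 6371.0088


def haversine(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class SiteGraph:
    """Connectivity network of collection sites with row-normalized weights."""

    graph: nx.Graph          # nodes = site ids, edge attr 'km'
    site_ids: list[str]
    W: np.ndarray            # (S, S) row-normalized adjacency

    def __post_init__(self) -> None:
        if not nx.is_connected(self.graph):
            raise ValueError("site graph must be connected")
        rows = self.W.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("weight rows must sum to 1")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_mst(f: SiteFreqMatrix) -> SiteGraph:
    """Minimum spanning tree of the collection sites on haversine distances.

    Ties are broken toward the lexicographically smaller site-id pair
    (Kruskal over edges sorted by (km, id pair)).
    """
    S = f.n_sites
    if S < 2:
        raise ValueError("need at least 2 collection sites")
    ids = f.site_ids
    edges = []
    for i in range(S):
        for j in range(i + 1, S):
            km = haversine(
                (f.latitudes[i], f.longitudes[i]), (f.latitudes[j], f.longitudes[j])
            )
            pair = tuple(sorted((ids[i], ids[j])))
            edges.append((km, pair, i, j))
    edges.sort(key=lambda e: (e[0], e[1]))

    g = nx.Graph()
    g.add_nodes_from(ids)
    parent = list(range(S))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for km, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            g.add_edge(ids[i], ids[j], km=km)
            if g.number_of_edges() == S - 1:
                break

    adj = nx.to_numpy_array(g, nodelist=ids, weight=None)
    W = adj / adj.sum(axis=1, keepdims=True)
    return SiteGraph(graph=g, site_ids=list(ids), W=W)


@dataclass
class SpcaResult:
    """Spatial PCA axes, site scores, and lagged (neighborhood-averaged) scores."""

    eigenvalues: np.ndarray       # signed, descending
    loadings: np.ndarray          # (L, n_axes) for retained axes
    scores: np.ndarray            # (S, n_retained)
    lagged_scores: np.ndarray     # (S, n_retained) = W @ scores
    score_variance: np.ndarray    # per retained axis
    autocorrelation: np.ndarray   # Moran-type I per retained axis
    n_retained: int

    def summary(self) -> str:
        lines = [f"sPCA: retained {self.n_retained} axes"]
        for a in range(self.n_retained):
            lines.append(
                f"  axis {a + 1}: eigenvalue {self.eigenvalues[a]:.4f} = "
                f"var {self.score_variance[a]:.4f} x I {self.autocorrelation[a]:.4f}"
            )
        return "\n".join(lines)


def spca(f: SiteFreqMatrix, g: SiteGraph, n_retain: int = 2) -> SpcaResult:
    """Spatial PCA of per-site allele frequencies over the connectivity graph.

    Columns of the frequency matrix are mean-imputed and centered; with the
    symmetrized weight ``Omega = (W + W') / 2`` the axes are eigenvectors of
    ``(1/S) f' Omega f``.  Each eigenvalue factors exactly into (score
    variance) x (Moran autocorrelation of the scores under Omega).  Lagged
    scores use the row-normalized W.
    """
    if f.n_sites != len(g.site_ids):
        raise ValueError("frequency rows must match graph nodes")
    X = np.asarray(f.freqs, dtype=float).copy()
    col_means = np.nanmean(X, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_means[nan_idx[1]]
    Xc = X - X.mean(axis=0)

    S = Xc.shape[0]
    omega = (g.W + g.W.T) / 2.0
    C = Xc.T @ omega @ Xc / S
    C = (C + C.T) / 2.0
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(-evals)
    evals = evals[order]
    evecs = evecs[:, order]

    n_pos = int((evals > 1e-12).sum())
    n_retained = min(n_retain, n_pos)
    axes = evecs[:, :n_retained]
    scores = Xc @ axes
    lagged = g.W @ scores

    var = (scores**2).sum(axis=0) / S
    with np.errstate(invalid="ignore", divide="ignore"):
        moran = np.einsum("sa,st,ta->a", scores, omega, scores) / np.maximum(
            (scores**2).sum(axis=0), 1e-300
        )
    return SpcaResult(
        eigenvalues=evals,
        loadings=axes,
        scores=scores,
        lagged_scores=lagged,
        score_variance=var,
        autocorrelation=moran,
        n_retained=n_retained,
    )


def geo_thin(
    individuals: list[IndividualMeta],
    min_km: float = 25.0,
    by: str = "accession",
) -> list[str]:
    """Greedy geographic thinning to a minimum pairwise distance.

    Sampling units are accessions by default (all individuals of an accession
    are kept or dropped together, located at the accession's first recorded
    coordinates); ``by='individual'`` thins individuals independently.  Units
    are scanned in stable id order and kept iff >= ``min_km`` from every
    previously kept unit.
    """
    if by not in ("accession", "individual"):
        raise ValueError(f"unknown thinning unit {by!r}")
    units: dict[str, list[IndividualMeta]] = {}
    for ind in individuals:
        if not ind.has_coordinates:
            continue
        key = (ind.accession or ind.id) if by == "accession" else ind.id
        units.setdefault(key, []).append(ind)

    kept_pos: list[tuple[float, float]] = []
    kept_ids: list[str] = []
    for key in sorted(units):
        members = units[key]
        pos = (members[0].latitude, members[0].longitude)
        if all(haversine(pos, p) >= min_km for p in kept_pos):
            kept_pos.append(pos)
            kept_ids.extend(sorted(m.id for m in members))
    return kept_ids


def geo_correlation(Q: np.ndarray, coords: np.ndarray) -> dict[str, float]:
    """r-squared of latitude and longitude regressed on ancestry proportions.

    The regression uses K-1 free ancestry components (the full Q matrix is
    collinear with the intercept).  ``coords`` is (n, 2) = (lat, lon).
    """
    Q = np.asarray(Q, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, K = Q.shape
    if K < 2:
        raise ValueError("need K >= 2 ancestry components")
    if n < K + 1:
        raise ValueError("need more individuals than ancestry components")
    X = np.column_stack([np.ones(n), Q[:, : K - 1]])
    out = {}
    for name, y in (("latitude", coords[:, 0]), ("longitude", coords[:, 1])):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = ((y - y.mean()) ** 2).sum()
        out[name] = float(1.0 - resid @ resid / sst) if sst > 0 else 0.0
    return out
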