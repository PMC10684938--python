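"""Identity-by-state genetic distances and neighbor-joining trees.

The IBS distance between two diploids at a locus is the probability that one
allele drawn from each differs: with p = dosage / 2, ``d = p_i (1 - p_j) +
(1 - p_i) p_j``, averaged over loci where both calls are present.  It is a
pseudo-metric (symmetric, zero self-distance) but can violate the triangle
inequality.

Neighbor joining uses the Studier-Keppler Q-criterion with deterministic
lexicographic tie-breaking; negative branch lengths are clamped to zero with
the deficit moved to the sibling branch, so leaf-to-leaf path lengths are
preserved on additive inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .snp import MISSING, SnpMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.nanmax(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.nanmax(np.abs(np.diag(self.values))) > 1e-12:
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_phylip(self, path) -> None:
        """Square PHYLIP distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{name[:10]:<10} {row}\n")

    def max_pair(self, candidates: list[str] | None = None) -> tuple[str, str, float]:
        """Globally maximal pair, optionally restricted to pairs touching a
        candidate; ties resolved toward the lexicographically smaller pair."""
        best: tuple[str, str, float] | None = None
        cand = set(candidates) if candidates is not None else None
        for i, j in itertools.combinations(range(self.n), 2):
            a, b = sorted((self.ids[i], self.ids[j]))
            if cand is not None and a not in cand and b not in cand:
                continue
            v = self.values[i, j]
            if best is None or v > best[2] or (v == best[2] and (a, b) < best[:2]):
                best = (a, b, float(v))
        if best is None:
            raise ValueError("no eligible pair")
        return best


def ibs_distance(m: SnpMatrix) -> DistanceMatrix:
    """Pairwise IBS distance matrix over shared non-missing loci."""
    if m.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    present = (m.calls != MISSING).astype(float)
    p = np.where(m.calls != MISSING, m.calls / 2.0, 0.0)
    shared = present @ present.T
    # sum over shared loci of p_i + p_j - 2 p_i p_j
    cross = (p * present) @ present.T  # sum of p_i over loci shared with j
    num = cross + cross.T - 2.0 * (p @ p.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(shared > 0, num / shared, np.nan)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(ids=m.ids, values=d)


@dataclass
class NjTree:
    """A (possibly rooted) tree as an undirected weighted graph.

    Leaf nodes are the taxon ids; internal nodes are integers.  ``root``
    names the node used for newick orientation (the final NJ join for
    unrooted trees).
    """

    graph: nx.Graph
    leaves: list[str]
    root: object = None

    def path_length(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def to_newick(self) -> str:
        root = self.root
        if root is None:
            root = next(n for n in self.graph if not isinstance(n, str))

        def render(node, parent) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            parts = []
            for c in sorted(children, key=str):
                sub = render(c, node)
                length = self.graph.edges[node, c]["length"]
                parts.append(f"{sub}:{length!r}")
            return "(" + ",".join(parts) + ")"

        return render(root, None) + ";"


def nj(d: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The node pair minimising ``(r - 2) d(i, j) - R_i - R_j`` is joined; ties
    are resolved toward the lexicographically smallest (smallest-leaf-id)
    pair.  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch.
    """
    if not d.is_complete():
        raise ValueError("distance matrix has missing entries; NJ needs complete data")
    if d.n < 3:
        raise ValueError("NJ needs at least 3 taxa")

    g = nx.Graph()
    active: list[object] = list(d.ids)
    g.add_nodes_from(active)
    # sort key per active node: its lexicographically smallest descendant leaf
    min_leaf: dict[object, str] = {t: t for t in active}
    D = {(a, b): d.values[i, j] for i, a in enumerate(d.ids) for j, b in enumerate(d.ids)}

    def dist(a, b):
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    next_internal = 0
    while len(active) > 3:
        r = len(active)
        R = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (r - 2) * dist(a, b) - R[a] - R[b]
            key = tuple(sorted((min_leaf[a], min_leaf[b])))
            if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                best = (q, key, a, b)
        _, _, a, b = best
        dab = dist(a, b)
        la = dab / 2.0 + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        u = next_internal
        next_internal += 1
        g.add_node(u)
        g.add_edge(u, a, length=la)
        g.add_edge(u, b, length=lb)
        min_leaf[u] = min(min_leaf[a], min_leaf[b])
        for c in active:
            if c not in (a, b):
                D[(u, c)] = (dist(a, c) + dist(b, c) - dab) / 2.0
        active = [c for c in active if c not in (a, b)] + [u]

    # final 3-way join via the three-point formulas
    a, b, c = sorted(active, key=lambda x: min_leaf[x])
    u = next_internal
    g.add_node(u)
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    for node, ln in ((a, la), (b, lb), (c, lc)):
        g.add_edge(u, node, length=max(ln, 0.0))
    return NjTree(graph=g, leaves=list(d.ids), root=u)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0.0:
        lb += la
        la = 0.0
    if lb < 0.0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def root_at_max_distance(
    t: NjTree, d: DistanceMatrix, candidates: list[str]
) -> NjTree:
    """Root the tree on the pendant edge of the candidate leaf involved in the
    globally maximal pairwise distance (outgroup rooting).

    The new root bisects the chosen leaf's pendant edge, so leaf-to-leaf path
    lengths are unchanged.
    """
    if not candidates:
        raise ValueError("no root candidates supplied")
    a, b, _ = d.max_pair(candidates)
    cand = set(candidates)
    leaf = a if a in cand else b
    if a in cand and b in cand:
        leaf = min(a, b)

    g = t.graph.copy()
    (nbr,) = list(g.neighbors(leaf))
    w = g.edges[leaf, nbr]["length"]
    g.remove_edge(leaf, nbr)
    root = "__root__"
    g.add_node(root)
    g.add_edge(root, leaf, length=w / 2.0)
    g.add_edge(root, nbr, length=w / 2.0)
    return NjTree(graph=g, leaves=list(t.leaves), root=root)
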