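"""Plastid SSR haplotype collapsing and minimum-spanning networks.

A haplotype is a complete 7-locus vector of microsatellite allele sizes;
individuals sharing the vector collapse onto one node annotated with carrier
count and nuclear-group composition.  The minimum spanning network is the
union of all minimum spanning trees over the haplotype distance matrix: an
edge of weight w is retained iff its endpoints are in different connected
components of the graph restricted to edges of weight < w.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .snp import MISSING, SsrTable


@dataclass
class HaploNode:
    """One unique SSR haplotype with its carriers."""

    haplotype: tuple[int, ...]
    carriers: list[str]
    composition: Counter = field(default_factory=Counter)

    @property
    def count(self) -> int:
        return len(self.carriers)


@dataclass
class HaploNetwork:
    nodes: list[HaploNode]
    graph: nx.Graph  # node keys = haplotype index; edge attr 'dist'

    def edge_set(self) -> set[tuple[int, int, int]]:
        return {
            (min(u, v), max(u, v), int(d["dist"]))
            for u, v, d in self.graph.edges(data=True)
        }

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for i, node in enumerate(self.nodes):
            g.nodes[i]["haplotype"] = ",".join(str(a) for a in node.haplotype)
            g.nodes[i]["count"] = node.count
        nx.write_graphml(g, path)

    def node_table(self):
        """Per-haplotype rows: haplotype string, carrier count, composition."""
        import pandas as pd

        rows = []
        for i, node in enumerate(self.nodes):
            rows.append(
                {
                    "node": i,
                    "haplotype": ",".join(str(a) for a in node.haplotype),
                    "count": node.count,
                    "composition": ";".join(
                        f"{g}:{c}" for g, c in sorted(node.composition.items())
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("node")


def collapse_haplotypes(
    s: SsrTable, group_labels: dict[str, str] | None = None
) -> list[HaploNode]:
    """Group identical complete SSR vectors into haplotype nodes.

    Individuals with missing calls must be excluded upstream
    (:meth:`SsrTable.complete_cases`); encountering one here is an error.
    """
    if (s.alleles == MISSING).any():
        raise ValueError("SSR table contains missing calls; drop incomplete cases first")
    groups = group_labels or {}
    seen: dict[tuple[int, ...], HaploNode] = {}
    for i, ind in enumerate(s.individuals):
        key = tuple(int(a) for a in s.alleles[i])
        node = seen.get(key)
        if node is None:
            node = seen.setdefault(key, HaploNode(haplotype=key, carriers=[]))
        node.carriers.append(ind)
        node.composition[groups.get(ind, "unknown")] += 1
    return list(seen.values())


def ssr_distance(a: tuple[int, ...], b: tuple[int, ...], mode: str = "loci") -> int:
    """Distance between haplotypes: differing-locus count (default) or the
    sum of absolute repeat-size differences (``mode='steps'``)."""
    av, bv = np.asarray(a), np.asarray(b)
    if mode == "loci":
        return int((av != bv).sum())
    if mode == "steps":
        return int(np.abs(av - bv).sum())
    raise ValueError(f"unknown distance mode {mode!r}")


def msn(nodes: list[HaploNode], mode: str = "loci") -> HaploNetwork:
    """Minimum spanning network (union of all MSTs) over haplotype nodes."""
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 haplotype nodes")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((ssr_distance(nodes[i].haplotype, nodes[j].haplotype, mode), i, j))
    edges.sort(key=lambda e: e[0])

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    g = nx.Graph()
    g.add_nodes_from(range(n))
    k = 0
    while k < len(edges):
        w = edges[k][0]
        batch = []
        while k < len(edges) and edges[k][0] == w:
            batch.append(edges[k])
            k += 1
        # edges in this weight class joining distinct components (as of < w) are
        # members of some MST; keep all of them, then merge components
        kept = [(wi, i, j) for wi, i, j in batch if find(i) != find(j)]
        for wi, i, j in kept:
            g.add_edge(i, j, dist=wi)
        for _, i, j in kept:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    return HaploNetwork(nodes=nodes, graph=g)
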