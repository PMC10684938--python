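"""IBS distances, neighbor joining, rooting, haplotype networks."""

import itertools

import numpy as np
import pytest

from obake.haplonet import HaploNode, collapse_haplotypes, msn, ssr_distance
from obake.snp import MISSING, SsrTable
from obake.trees import DistanceMatrix, ibs_distance, nj, root_at_max_distance

from conftest import make_matrix


class TestIbsDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(0, 2, 1.0), (1, 1, 0.5), (0, 0, 0.0), (2, 2, 0.0), (0, 1, 0.5), (1, 2, 0.5)],
    )
    def test_single_locus_values(self, a, b, expected):
        d = ibs_distance(make_matrix([[a], [b]]))
        assert d.values[0, 1] == pytest.approx(expected)

    def test_mean_over_shared_loci_only(self):
        d = ibs_distance(make_matrix([[0, 2, MISSING], [2, MISSING, 2]]))
        assert d.values[0, 1] == pytest.approx(1.0)  # only locus 1 shared

    def test_zero_shared_loci_missing(self):
        d = ibs_distance(make_matrix([[0, MISSING], [MISSING, 2]]))
        assert np.isnan(d.values[0, 1])

    def test_symmetry_and_zero_diagonal(self, rng):
        calls = rng.integers(-1, 3, size=(10, 50)).astype(np.int8)
        d = ibs_distance(make_matrix(calls))
        assert np.allclose(d.values, d.values.T, equal_nan=True)
        assert np.allclose(np.diag(d.values), 0.0)


def path_lengths(tree):
    out = {}
    for a, b in itertools.combinations(sorted(tree.leaves), 2):
        out[(a, b)] = tree.path_length(a, b)
    return out


class TestNj:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1, B:2):1, C:3, D:4) -> additive distances
        ids = ["A", "B", "C", "D"]
        vals = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        d = DistanceMatrix(ids, vals)
        tree = nj(d)
        pl = path_lengths(tree)
        for (a, b) in pl:
            i, j = ids.index(a), ids.index(b)
            assert pl[(a, b)] == pytest.approx(vals[i, j], abs=1e-9)
        # AB|CD topology: the A-B path avoids the C/D pendant edges
        assert tree.path_length("A", "B") == pytest.approx(3.0)

    def test_three_taxon_closed_form(self):
        vals = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj(DistanceMatrix(["A", "B", "C"], vals))
        # l_A = (3 + 4 - 5)/2 = 1, l_B = 2, l_C = 3
        assert tree.path_length("A", "B") == pytest.approx(3.0)
        assert tree.path_length("A", "C") == pytest.approx(4.0)
        assert tree.path_length("B", "C") == pytest.approx(5.0)

    def test_random_additive_matrix_round_trips(self, rng):
        # random caterpillar tree with positive branch lengths
        n = 7
        ids = [f"t{i}" for i in range(n)]
        pend = rng.uniform(0.5, 2.0, n)
        internal = rng.uniform(0.2, 1.0, n - 2)
        # distances on a path topology: leaves hang off a chain of internals
        pos = np.concatenate([[0.0], np.cumsum(internal)])  # chain coordinates
        attach = np.array([0, 0] + list(range(1, n - 2)) + [n - 3])
        vals = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            chain = abs(pos[attach[i]] - pos[attach[j]])
            vals[i, j] = vals[j, i] = pend[i] + pend[j] + chain
        tree = nj(DistanceMatrix(ids, vals))
        pl = path_lengths(tree)
        for (a, b), v in pl.items():
            assert v == pytest.approx(vals[ids.index(a), ids.index(b)], abs=1e-9)

    def test_ultrametric_ties_deterministic(self):
        vals = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(["a", "b", "c", "d"], vals)
        assert nj(d).to_newick() == nj(d).to_newick()

    def test_incomplete_matrix_rejected(self):
        vals = np.array([[0.0, np.nan, 1.0], [np.nan, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj(DistanceMatrix(["a", "b", "c"], vals))

    def test_branch_lengths_nonnegative(self, rng):
        # noisy (non-additive) matrix still yields nonnegative branches
        base = rng.uniform(0.5, 1.5, size=(6, 6))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 0.0)
        tree = nj(DistanceMatrix([f"x{i}" for i in range(6)], vals))
        assert all(d["length"] >= 0 for _, _, d in tree.graph.edges(data=True))


class TestRooting:
    def _setup(self):
        ids = ["A", "B", "C", "X"]
        vals = np.array(
            [
                [0.0, 3.0, 5.0, 9.0],
                [3.0, 0.0, 6.0, 10.0],
                [5.0, 6.0, 0.0, 11.0],
                [9.0, 10.0, 11.0, 0.0],
            ]
        )
        d = DistanceMatrix(ids, vals)
        return d, nj(d)

    def test_roots_on_max_distance_candidate(self):
        d, tree = self._setup()
        rooted = root_at_max_distance(tree, d, ["X"])
        assert rooted.root == "__root__"
        assert rooted.graph.has_edge("__root__", "X")

    def test_tie_prefers_lexicographic_candidate(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 2.0
        vals[0, 2] = vals[2, 0] = 2.0
        vals[1, 2] = vals[2, 1] = 1.0
        d = DistanceMatrix(["b", "a", "c"], vals)
        tree = nj(DistanceMatrix(["b", "a", "c"], vals))
        rooted = root_at_max_distance(tree, d, ["a", "b"])
        # max pairs (a,b) and (b,c) tie at 2.0; pair (a,b) wins, leaf 'a' chosen
        assert rooted.graph.has_edge("__root__", "a")

    def test_rooting_preserves_leaf_path_lengths(self):
        d, tree = self._setup()
        before = path_lengths(tree)
        rooted = root_at_max_distance(tree, d, ["X"])
        after = path_lengths(rooted)
        for pair, v in before.items():
            assert after[pair] == pytest.approx(v, abs=1e-12)

    def test_empty_candidates_errors(self):
        d, tree = self._setup()
        with pytest.raises(ValueError):
            root_at_max_distance(tree, d, [])


class TestCollapseHaplotypes:
    def test_two_distinct_vectors(self):
        t = SsrTable(
            individuals=["a", "b", "c", "d"],
            loci=[f"l{i}" for i in range(3)],
            alleles=np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 4]]),
        )
        nodes = collapse_haplotypes(t)
        assert sorted(n.count for n in nodes) == [1, 3]

    def test_all_identical_single_node(self):
        t = SsrTable(["a", "b"], ["l1"], np.array([[5], [5]]))
        assert len(collapse_haplotypes(t)) == 1

    def test_matches_dictionary_oracle(self, rng):
        alleles = rng.integers(1, 4, size=(10, 4))
        t = SsrTable([f"i{k}" for k in range(10)], [f"l{i}" for i in range(4)], alleles)
        nodes = collapse_haplotypes(t)
        oracle: dict = {}
        for k in range(10):
            oracle.setdefault(tuple(alleles[k]), []).append(f"i{k}")
        assert {n.haplotype: sorted(n.carriers) for n in nodes} == {
            h: sorted(c) for h, c in oracle.items()
        }

    def test_carrier_counts_conserve_individuals(self, rng):
        alleles = rng.integers(1, 3, size=(20, 4))
        t = SsrTable([f"i{k}" for k in range(20)], ["a", "b", "c", "d"], alleles)
        assert sum(n.count for n in collapse_haplotypes(t)) == 20

    def test_missing_calls_rejected(self):
        t = SsrTable(["a"], ["l1", "l2"], np.array([[5, MISSING]]))
        with pytest.raises(ValueError):
            collapse_haplotypes(t)


def brute_force_msn_edges(nodes, mode="loci"):
    """Union of all minimum spanning trees by enumeration (small n)."""
    n = len(nodes)
    edges = [
        (i, j, ssr_distance(nodes[i].haplotype, nodes[j].haplotype, mode))
        for i, j in itertools.combinations(range(n), 2)
    ]
    import networkx as nx

    best = np.inf
    trees = []
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from([(i, j) for i, j, _ in subset])
        if not nx.is_connected(g):
            continue
        w = sum(d for _, _, d in subset)
        if w < best - 1e-12:
            best = w
            trees = [subset]
        elif abs(w - best) <= 1e-12:
            trees.append(subset)
    out = set()
    for t in trees:
        for i, j, d in t:
            out.add((min(i, j), max(i, j), d))
    return out


def _nodes(vectors):
    return [HaploNode(haplotype=tuple(v), carriers=[f"c{i}"]) for i, v in enumerate(vectors)]


class TestMsn:
    def test_all_pairs_tied_keeps_triangle(self):
        # every pair differs at 2 loci: all three edges tie and are retained
        nodes = _nodes([(0, 0), (1, 1), (2, 2)])
        net = msn(nodes)
        assert net.graph.number_of_edges() == 3

    def test_chain_distances(self):
        # distances 1, 1, 2: only the two distance-1 edges survive
        nodes = _nodes([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        net = msn(nodes)
        assert net.edge_set() == {(0, 1, 1), (1, 2, 1)}

    def test_matches_bruteforce_union_of_msts(self, rng):
        vectors = rng.integers(0, 3, size=(6, 4))
        nodes = _nodes(vectors)
        net = msn(nodes)
        assert net.edge_set() == brute_force_msn_edges(nodes)

    def test_network_connected(self, rng):
        import networkx as nx

        nodes = _nodes(rng.integers(0, 4, size=(8, 5)))
        assert nx.is_connected(msn(nodes).graph)

    def test_steps_mode(self):
        nodes = _nodes([(100,), (103,)])
        net = msn(nodes, mode="steps")
        assert net.edge_set() == {(0, 1, 3)}


class TestNjCrossCheck:
    def test_agrees_with_independent_nj_implementation(self, rng):
        """Dual route: our NJ vs scikit-bio's on a random additive matrix."""
        import io

        from skbio import DistanceMatrix as SkbioDM, TreeNode
        from skbio.tree import nj as skbio_nj

        n = 6
        ids = [f"t{i}" for i in range(n)]
        # random additive matrix from a random tree: leaves attached to a chain
        pend = rng.uniform(0.5, 2.0, n)
        internal = rng.uniform(0.2, 1.0, n - 2)
        pos = np.concatenate([[0.0], np.cumsum(internal)])
        attach = np.array([0, 0] + list(range(1, n - 2)) + [n - 3])
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = pend[i] + pend[j] + abs(pos[attach[i]] - pos[attach[j]])

        ours = nj(DistanceMatrix(ids, vals))
        theirs = skbio_nj(SkbioDM(vals, ids))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = ids[i], ids[j]
                ref = theirs.find(a).distance(theirs.find(b))
                assert ours.path_length(a, b) == pytest.approx(ref, abs=1e-9)
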