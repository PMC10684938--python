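"""Geographic utilities and spatial PCA."""

import itertools

import networkx as nx
import numpy as np
import pytest

from obake.snp import IndividualMeta, SiteFreqMatrix
from obake.spatial import build_mst, geo_correlation, geo_thin, haversine, spca


def freq_matrix(lats, lons, freqs, n=None):
    S = len(lats)
    return SiteFreqMatrix(
        site_ids=[f"s{i}" for i in range(S)],
        latitudes=np.asarray(lats, dtype=float),
        longitudes=np.asarray(lons, dtype=float),
        n=np.asarray(n if n is not None else [2] * S),
        freqs=np.asarray(freqs, dtype=float),
    )


class TestHaversine:
    def test_identical_points(self):
        assert haversine((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_one_degree_longitude_at_equator(self):
        # 2 pi R / 360
        assert haversine((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetry(self):
        a, b = (12.3, -4.5), (-33.0, 151.0)
        assert haversine(a, b) == pytest.approx(haversine(b, a))


def brute_force_mst_length(f):
    """Minimum spanning-tree total length by enumeration (<= 7 nodes)."""
    S = f.n_sites
    edges = []
    for i, j in itertools.combinations(range(S), 2):
        km = haversine((f.latitudes[i], f.longitudes[i]), (f.latitudes[j], f.longitudes[j]))
        edges.append((i, j, km))
    best = np.inf
    for subset in itertools.combinations(edges, S - 1):
        g = nx.Graph()
        g.add_nodes_from(range(S))
        g.add_edges_from([(i, j) for i, j, _ in subset])
        if nx.is_connected(g):
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestBuildMst:
    def test_collinear_chain(self):
        f = freq_matrix([0.0, 0.009, 0.027], [0.0] * 3, np.zeros((3, 2)))
        g = build_mst(f)
        assert g.graph.has_edge("s0", "s1") and g.graph.has_edge("s1", "s2")
        assert not g.graph.has_edge("s0", "s2")

    def test_two_sites_single_edge(self):
        f = freq_matrix([0.0, 1.0], [0.0, 0.0], np.zeros((2, 2)))
        assert build_mst(f).graph.number_of_edges() == 1

    def test_matches_bruteforce_total_length(self, rng):
        lats = rng.uniform(-10, 10, 6)
        lons = rng.uniform(-10, 10, 6)
        f = freq_matrix(lats, lons, np.zeros((6, 2)))
        g = build_mst(f)
        total = sum(d["km"] for _, _, d in g.graph.edges(data=True))
        assert total == pytest.approx(brute_force_mst_length(f), abs=1e-9)

    def test_weight_rows_sum_to_one(self, rng):
        f = freq_matrix(rng.uniform(0, 5, 5), rng.uniform(0, 5, 5), np.zeros((5, 2)))
        assert np.allclose(build_mst(f).W.sum(axis=1), 1.0)


class TestSpca:
    def _cline(self, S=10, L=40, noise=0.0, rng=None):
        lats = np.linspace(0.0, 9.0, S)
        lons = np.zeros(S)
        base = np.linspace(0.1, 0.9, S)[:, None] * np.ones((1, L))
        if noise and rng is not None:
            base = np.clip(base + rng.normal(0, noise, base.shape), 0, 1)
        return freq_matrix(lats, lons, base)

    def test_cline_lagged_scores_monotone_in_latitude(self):
        f = self._cline()
        g = build_mst(f)
        res = spca(f, g)
        lag1 = res.lagged_scores[:, 0]
        diffs = np.diff(lag1)
        # monotone in latitude up to sign (chain endpoints tie with neighbours)
        assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)
        assert abs(lag1[-1] - lag1[0]) > 0.1

    def test_permutation_reduces_leading_eigenvalue(self, rng):
        f = self._cline(noise=0.02, rng=rng)
        g = build_mst(f)
        lead = spca(f, g).eigenvalues[0]
        perm = rng.permutation(f.n_sites)
        f_perm = freq_matrix(f.latitudes, f.longitudes, f.freqs[perm])
        assert spca(f_perm, g).eigenvalues[0] < lead

    def test_constant_frequencies_zero_eigenvalues(self):
        f = freq_matrix([0.0, 1.0, 2.0], [0.0] * 3, np.full((3, 5), 0.4))
        g = build_mst(f)
        res = spca(f, g)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.n_retained == 0

    def test_eigenvalue_equals_variance_times_autocorrelation(self, rng):
        f = self._cline(noise=0.05, rng=rng)
        g = build_mst(f)
        res = spca(f, g)
        for a in range(res.n_retained):
            assert res.eigenvalues[a] == pytest.approx(
                res.score_variance[a] * res.autocorrelation[a], abs=1e-8
            )


def _inds(coords):
    return [
        IndividualMeta(id=f"i{k:02d}", latitude=lat, longitude=lon)
        for k, (lat, lon) in enumerate(coords)
    ]


class TestGeoThin:
    def test_close_pair_keeps_one(self):
        kept = geo_thin(_inds([(0.0, 0.0), (0.0, 0.09)]), min_km=25.0)
        assert kept == ["i00"]

    def test_all_far_apart_kept(self):
        kept = geo_thin(_inds([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]), min_km=25.0)
        assert len(kept) == 3

    def test_matches_greedy_oracle(self):
        coords = [(0.0, 0.0), (0.1, 0.0), (0.3, 0.0), (0.5, 0.0), (5.0, 5.0)]
        inds = _inds(coords)
        kept = geo_thin(inds, min_km=25.0)
        oracle = []
        for ind in sorted(inds, key=lambda x: x.id):
            pos = (ind.latitude, ind.longitude)
            if all(haversine(pos, (o.latitude, o.longitude)) >= 25.0 for o in oracle):
                oracle.append(ind)
        assert kept == [o.id for o in oracle]

    def test_pairwise_distances_at_least_min_km(self, rng):
        coords = [(lat, lon) for lat, lon in zip(rng.uniform(0, 2, 30), rng.uniform(0, 2, 30))]
        inds = _inds(coords)
        kept = set(geo_thin(inds, min_km=25.0))
        kept_inds = [i for i in inds if i.id in kept]
        for a, b in itertools.combinations(kept_inds, 2):
            assert haversine((a.latitude, a.longitude), (b.latitude, b.longitude)) >= 25.0


class TestGeoCorrelation:
    def test_perfect_linear_relation(self):
        q1 = np.linspace(0.1, 0.9, 20)
        Q = np.column_stack([q1, 1 - q1])
        coords = np.column_stack([2.0 * q1 + 1.0, np.ones(20)])
        out = geo_correlation(Q, coords)
        assert out["latitude"] == pytest.approx(1.0)

    def test_independent_q_near_zero(self, rng):
        q1 = rng.uniform(0.1, 0.9, 400)
        Q = np.column_stack([q1, 1 - q1])
        coords = np.column_stack([rng.uniform(0, 10, 400), rng.uniform(0, 10, 400)])
        out = geo_correlation(Q, coords)
        assert out["latitude"] < 0.03

    def test_k2_reduces_to_squared_pearson(self, rng):
        q1 = rng.uniform(0, 1, 50)
        Q = np.column_stack([q1, 1 - q1])
        lat = 3 * q1 + rng.normal(0, 0.5, 50)
        coords = np.column_stack([lat, lat])
        out = geo_correlation(Q, coords)
        r = np.corrcoef(q1, lat)[0, 1]
        assert out["latitude"] == pytest.approx(r**2, abs=1e-10)

    def test_too_few_individuals_errors(self):
        with pytest.raises(ValueError):
            geo_correlation(np.array([[0.5, 0.5], [0.6, 0.4]]), np.zeros((2, 2)))


class TestGeoThinAccessions:
    def test_accession_pair_kept_or_dropped_together(self):
        from obake.snp import IndividualMeta

        inds = [
            IndividualMeta(id="a.001", accession="A", latitude=0.0, longitude=0.0),
            IndividualMeta(id="a.002", accession="A", latitude=0.0, longitude=0.0),
            IndividualMeta(id="b.001", accession="B", latitude=0.05, longitude=0.0),
            IndividualMeta(id="b.002", accession="B", latitude=0.05, longitude=0.0),
            IndividualMeta(id="c.001", accession="C", latitude=5.0, longitude=0.0),
        ]
        kept = geo_thin(inds, min_km=25.0, by="accession")
        # accession B (~5.6 km from A) is dropped whole; A and C kept whole
        assert kept == ["a.001", "a.002", "c.001"]

    def test_unknown_unit_errors(self):
        with pytest.raises(ValueError):
            geo_thin([], by="site")


class TestSpcaEndToEnd:
    def test_geographic_structure_recovered_from_panel(self):
        """Thin -> pool by site -> MST -> sPCA recovers the latitudinal cline."""
        from obake.filters import filter_individuals, filter_sites, pool_by_site, thin_sites
        from obake.simulate import SimSpec, SubpopSpec, simulate_panel

        spec = SimSpec(
            seed=17, n_loci=800,
            subpops=(
                SubpopSpec("NW", (14.0, -5.0), n=20, f_sub=0.05, f_is=0.3),
                SubpopSpec("PA", (0.0, 20.0), n=20, f_sub=0.05, f_is=0.3),
                SubpopSpec("SO", (-20.0, 35.0), n=20, f_sub=0.05, f_is=0.3),
            ),
            outgroups={}, pedigrees=(), missing_rate=0.02,
        )
        m, _, _ = simulate_panel(spec)
        m = thin_sites(filter_sites(filter_individuals(m)), 100)
        f = pool_by_site(m)
        res = spca(f, build_mst(f), n_retain=2)
        assert res.n_retained == 2
        r = np.corrcoef(res.scores[:, 0], f.latitudes)[0, 1]
        assert abs(r) > 0.8
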