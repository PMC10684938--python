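"""Ground-truthed synthetic panel generator."""

import hashlib

import numpy as np
import pytest

from obake.diversity import f_statistics, group_freqs
from obake.filters import filter_individuals, filter_sites
from obake.io import read_vcf, read_metadata_csv, read_ssr_csv
from obake.simulate import (
    PedigreeSpec,
    SimSpec,
    SubpopSpec,
    SSR_FOUNDERS,
    emit,
    sim_frequencies,
    sim_individual,
    sim_pedigree,
    sim_plastid,
    simulate_panel,
)
from obake.snp import MISSING


def flat_two_group(F, fis=0.0, seed=1, L=2000, n=50):
    """Two demes directly under a near-uniform ancestral pool."""
    return SimSpec(
        seed=seed,
        n_loci=L,
        species_f={"longistaminata": 1e-6, "sativa": 1e-6, "barthii_glaberrima": 1e-6},
        subpops=(
            SubpopSpec("A", (0.0, 0.0), n=n, f_sub=F, f_is=fis),
            SubpopSpec("B", (10.0, 10.0), n=n, f_sub=F, f_is=fis),
        ),
        outgroups={},
        pedigrees=(),
        gradient_km=None,
        missing_rate=0.0,
    )


class TestSimFrequencies:
    def test_low_divergence_tracks_parent(self):
        spec = SimSpec(seed=3, n_loci=2000, species_f={"longistaminata": 1e-4, "sativa": 0.3, "barthii_glaberrima": 0.35})
        rng = np.random.default_rng(3)
        f = sim_frequencies(spec, rng)
        assert np.abs(f.pools["longistaminata"] - f.ancestral).max() < 0.05

    def test_species_divergence_realized(self):
        # two demes at F = 0.3: realized mean per-locus F_ST within 0.02
        m, _, _ = simulate_panel(flat_two_group(0.3, seed=4, L=4000))
        gf = group_freqs(m, {i.id: i.id[0] for i in m.individuals})
        fst = f_statistics(gf).stats.loc["F_ST", "mean"]
        assert fst == pytest.approx(0.3, abs=0.02)

    def test_fixed_seed_reproducible(self):
        spec = SimSpec(seed=9, n_loci=100)
        f1 = sim_frequencies(spec, np.random.default_rng(9))
        f2 = sim_frequencies(spec, np.random.default_rng(9))
        assert np.array_equal(f1.ancestral, f2.ancestral)
        assert all(np.array_equal(f1.demes[k], f2.demes[k]) for k in f1.demes)


class TestSimIndividual:
    def test_full_inbreeding_no_heterozygotes(self, rng):
        p = rng.uniform(0.2, 0.8, 500)[None, :]
        dosage, _ = sim_individual(p, np.array([1.0]), f_is=1.0, rng=rng)
        assert not np.any(dosage == 1)

    def test_outbred_heterozygosity_near_half(self, rng):
        p = np.full((1, 4000), 0.5)
        dosage, _ = sim_individual(p, np.array([1.0]), f_is=0.0, rng=rng)
        assert (dosage == 1).mean() == pytest.approx(0.5, abs=0.03)

    def test_fis_recovered_by_estimator(self):
        m, _, _ = simulate_panel(flat_two_group(0.02, fis=0.44, seed=12))
        gf = group_freqs(m, {i.id: i.id[0] for i in m.individuals})
        fis = f_statistics(gf).stats.loc["F_IS", "mean"]
        assert fis == pytest.approx(0.44, abs=0.03)


class TestSimPedigree:
    @staticmethod
    def _freqs(seed=5, L=1000):
        spec = SimSpec(seed=seed, n_loci=L)
        return sim_frequencies(spec, np.random.default_rng(seed))

    def test_f1_ancestry_exactly_half(self):
        freqs = self._freqs()
        rng = np.random.default_rng(0)
        _, fracs = sim_pedigree(freqs, PedigreeSpec("F1", maternal="sativa"), rng)
        assert fracs["sativa"] == pytest.approx(0.5)
        assert fracs["longistaminata"] == pytest.approx(0.5)

    def test_bc1_mean_ancestry_quarter(self):
        freqs = self._freqs()
        rng = np.random.default_rng(1)
        fr = [
            sim_pedigree(freqs, PedigreeSpec("BC1:longistaminata", maternal="longistaminata"), rng)[1][
                "sativa"
            ]
            for _ in range(40)
        ]
        assert np.mean(fr) == pytest.approx(0.25, abs=0.02)

    def test_ril_heterozygosity_collapses(self):
        freqs = self._freqs()
        rng = np.random.default_rng(2)
        f1, _ = sim_pedigree(freqs, PedigreeSpec("F1", maternal="sativa"), rng)
        het_f1 = np.mean(
            [(p.alleles[0] != p.alleles[1]).mean() for p, _ in
             (sim_pedigree(freqs, PedigreeSpec("F1", maternal="sativa"), rng) for _ in range(10))]
        )
        het_ril = np.mean(
            [(p.alleles[0] != p.alleles[1]).mean() for p, _ in
             (sim_pedigree(freqs, PedigreeSpec("RIL5", maternal="sativa"), rng) for _ in range(10))]
        )
        assert het_ril < 0.1 * het_f1

    def test_bad_scheme_reports_position(self):
        freqs = self._freqs(L=10)
        with pytest.raises(ValueError, match="position"):
            sim_pedigree(freqs, PedigreeSpec("F1-XX", maternal="sativa"), np.random.default_rng(0))


class TestSimPlastid:
    def test_zero_mutation_rate_returns_founders(self):
        spec = SimSpec(seed=1, ssr_mutation_rate=0.0)
        haps = sim_plastid(spec, ["sativa", "longistaminata"], np.random.default_rng(0))
        assert tuple(haps[0]) == SSR_FOUNDERS["sativa"]
        assert tuple(haps[1]) == SSR_FOUNDERS["longistaminata"]

    def test_hybrid_inherits_maternal_founder_unchanged(self):
        spec = SimSpec(seed=1, ssr_mutation_rate=2.0)
        haps = sim_plastid(
            spec, ["longistaminata"], np.random.default_rng(0), mutate=[False]
        )
        assert tuple(haps[0]) == SSR_FOUNDERS["longistaminata"]

    def test_founders_separated_by_three_loci(self):
        names = list(SSR_FOUNDERS)
        for a in names:
            for b in names:
                if a < b:
                    diff = sum(
                        x != y for x, y in zip(SSR_FOUNDERS[a], SSR_FOUNDERS[b])
                    )
                    assert diff >= 3

    def test_no_cross_species_sharing_at_low_rate(self):
        spec = SimSpec(seed=2, ssr_mutation_rate=0.5)
        rng = np.random.default_rng(2)
        lineages = ["longistaminata"] * 200 + ["sativa"] * 200
        haps = sim_plastid(spec, lineages, rng)
        set_a = {tuple(h) for h in haps[:200]}
        set_b = {tuple(h) for h in haps[200:]}
        assert not (set_a & set_b)


class TestEmit:
    def test_round_trip_through_readers(self, tmp_path):
        spec = SimSpec(seed=21, n_loci=120)
        paths = emit(spec, tmp_path)
        m, ssr, truth = simulate_panel(spec)
        back = read_vcf(paths["vcf"], read_metadata_csv(paths["metadata"]))
        assert np.array_equal(back.calls, m.calls)
        assert np.array_equal(back.depths, m.depths)
        assert back.ids == m.ids
        ssr_back = read_ssr_csv(paths["ssr"])
        assert np.array_equal(ssr_back.alleles, ssr.alleles)
        labels = {i.id: i.species_label for i in back.individuals}
        assert labels == {i.id: i.species_label for i in m.individuals}

    def test_missing_rate_realized(self):
        spec = SimSpec(seed=22, n_loci=2000, missing_rate=0.1)
        m, _, _ = simulate_panel(spec)
        assert (m.calls == MISSING).mean() == pytest.approx(0.10, abs=0.01)

    def test_depth_mean_realized(self):
        spec = SimSpec(seed=23, n_loci=1000, depth_mean=30.0, missing_rate=0.0)
        m, _, _ = simulate_panel(spec)
        assert m.depths.sum(axis=2).mean() == pytest.approx(30.0, abs=1.0)

    def test_byte_identical_across_runs(self, tmp_path):
        spec = SimSpec(seed=24, n_loci=80)
        p1 = emit(spec, tmp_path / "a")
        p2 = emit(spec, tmp_path / "b")
        for key in p1:
            h1 = hashlib.sha256(p1[key].read_bytes()).hexdigest()
            h2 = hashlib.sha256(p2[key].read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_truth_dimensions_match_panel(self):
        spec = SimSpec(seed=25, n_loci=50)
        m, ssr, truth = simulate_panel(spec)
        assert len(truth.frame) == m.n_individuals
        assert set(truth.frame.index) == set(m.ids)

    def test_ancient_admixture_encoded_in_truth(self):
        m, _, truth = simulate_panel(SimSpec(seed=26, n_loci=50))
        southern = truth.frame[truth.frame["subpop"] == "Southern"]
        assert np.allclose(southern["q_sativa"], 0.037)
        northwestern = truth.frame[truth.frame["subpop"] == "Northwestern"]
        assert np.allclose(northwestern["q_sativa"], 0.0)
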