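"""Synthetic genotype panels emulating a mixed wild/outgroup rice study design.

The generator produces, with full ground truth: one outcrossing wild species
(three geographically structured subpopulations under a Balding-Nichols
hierarchy, logistic ancestry mixing along geography, subpop-specific
inbreeding, optional low-level "ancient" domesticated admixture), two to
three diverged selfing outgroup pools, pedigreed interspecific hybrids (F1,
F2, backcrosses, selfed RIL lineages) with per-locus ancestry tracking,
maternally inherited plastid SSR haplotypes under stepwise mutation, and a
missing-data/read-depth observation model.

Calibration: a species or subpopulation requested at divergence F from its
parent pool draws frequencies from Beta(p (1-c)/c, (1-p)(1-c)/c) with
``c = 2F / (1 + F)``, so that two sister populations both at F show a
realized pairwise F_ST of about F under the sample-size-corrected estimators
in :mod:`obake.diversity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_metadata_csv, write_ssr_csv, write_vcf
from .snp import MISSING, IndividualMeta, SiteMeta, SnpMatrix, SsrTable
from .spatial import haversine

SPECIES_POOLS = ("longistaminata", "sativa", "barthii_glaberrima")

#: plastid SSR founder haplotypes; any two species differ at >= 3 loci
SSR_FOUNDERS = {
    "longistaminata": (100, 110, 120, 130, 140, 150, 160),
    "sativa": (103, 113, 123, 130, 140, 150, 160),
    "barthii_glaberrima": (100, 110, 120, 134, 144, 154, 160),
}


@dataclass(frozen=True)
class SubpopSpec:
    """One wild-species subpopulation."""

    name: str
    center: tuple[float, float]  # (lat, lon)
    n: int
    f_sub: float = 0.02
    f_is: float = 0.3
    ancient_sativa: float = 0.0  # fixed sativa-pool fraction blended into q


@dataclass(frozen=True)
class PedigreeSpec:
    """A crossing scheme between the wild species and the sativa pool.

    ``scheme`` grammar: ``F1`` | ``F2`` | ``BC1:<species>`` | ``BC2:<species>``
    | ``RIL[k]`` (F1 followed by k selfing generations, default 6), or an
    explicit chain like ``F1-BC:<species>-SELF2``.  ``maternal`` is the
    species of the original F1 mother (plastid donor).
    """

    scheme: str
    maternal: str = "sativa"
    count: int = 1
    label: str = "control_hybrid"  # species_label given to the emitted entries
    at_subpop: str | None = None   # place at this subpop's sites (field hybrids)


@dataclass(frozen=True)
class SimSpec:
    """Full panel design.  ``seed`` is mandatory for any emitted dataset."""

    seed: int
    n_loci: int = 500
    species_f: dict = field(
        default_factory=lambda: {
            "longistaminata": 0.30,
            "sativa": 0.30,
            "barthii_glaberrima": 0.35,
        }
    )
    subpops: tuple[SubpopSpec, ...] = (
        SubpopSpec("Northwestern", (14.0, -5.0), n=28, f_sub=0.02, f_is=0.28),
        SubpopSpec("PanAfrica", (0.0, 20.0), n=28, f_sub=0.02, f_is=0.29),
        SubpopSpec("Southern", (-20.0, 35.0), n=24, f_sub=0.02, f_is=0.44,
                   ancient_sativa=0.037),
    )
    outgroups: dict = field(
        default_factory=lambda: {"sativa": 20, "barthii_glaberrima": 20}
    )
    outgroup_f_is: float = 0.95  # selfing species
    bg_split_f: float = 0.05     # barthii vs glaberrima around their pool
    sativa_split_f: float = 0.10  # two domesticated sativa demes (indica/japonica-like)
    gradient_km: float | None = 800.0  # logistic ancestry-mixing scale; None = pure
    pedigrees: tuple[PedigreeSpec, ...] = (
        PedigreeSpec("F1", maternal="sativa", count=1),
        PedigreeSpec("F2", maternal="sativa", count=2),
        # backcross-derived RILs: mostly-sativa lines with ~12% wild ancestry,
        # whose minimum minority fraction calibrates the hybrid band
        PedigreeSpec("F1-BC:sativa-SELF4", maternal="sativa", count=3),
        PedigreeSpec("F1", maternal="longistaminata", count=1,
                     label="longistaminata", at_subpop="PanAfrica"),
        PedigreeSpec("BC1:longistaminata", maternal="longistaminata", count=2,
                     label="longistaminata", at_subpop="PanAfrica"),
        PedigreeSpec("BC2:longistaminata", maternal="longistaminata", count=1,
                     label="longistaminata", at_subpop="Southern"),
    )
    missing_rate: float = 0.05
    depth_mean: float = 30.0
    depth_overdispersion: float = 6.0
    ssr_mutation_rate: float = 0.5  # expected stepwise mutations per lineage
    coord_jitter: float = 0.15

    def __post_init__(self) -> None:
        for name, f in self.species_f.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"species F for {name} must be in (0, 1)")
        for sp in self.subpops:
            if not 0.0 < sp.f_sub < 1.0:
                raise ValueError("subpop F must be in (0, 1)")


@dataclass
class FreqTable:
    """Hierarchical allele frequencies: ancestral, species pools, leaf demes."""

    ancestral: np.ndarray
    pools: dict[str, np.ndarray]
    demes: dict[str, np.ndarray]  # subpop name or outgroup deme -> (L,)


@dataclass
class SimTruth:
    """Ground truth for an emitted panel."""

    frame: pd.DataFrame  # per individual: labels, coords, true q components
    locus_origins: dict[str, np.ndarray] = field(default_factory=dict)

    def q_species(self) -> pd.DataFrame:
        return self.frame[["q_longistaminata", "q_sativa", "q_barthii_glaberrima"]]


# ---------------------------------------------------------------------------
# frequency hierarchy
# ---------------------------------------------------------------------------


# Monte-Carlo calibration of the Balding-Nichols concentration parameter c
# against the across-loci mean of per-locus F_ST between two sister demes of
# 50 diploids each (uniform(0.05, 0.95) ancestral frequencies, 60k loci,
# the sample-size-corrected estimators of obake.diversity): requesting
# divergence F draws with the c whose realized mean per-locus F_ST equals F.
_CAL_C = np.array(
    [0.002, 0.005, 0.01, 0.02, 0.04, 0.06, 0.09, 0.13, 0.18, 0.25, 0.35, 0.5, 0.6, 0.7]
)
_CAL_F = np.array(
    [0.00103, 0.00246, 0.00486, 0.00967, 0.01920, 0.02840, 0.04219, 0.05992,
     0.08245, 0.11347, 0.15966, 0.23259, 0.29565, 0.36851]
)


def _bn_concentration(f: float) -> float:
    """Drift parameter c giving realized mean per-locus F_ST of about f."""
    if f <= _CAL_F[0]:
        return float(f * _CAL_C[0] / _CAL_F[0])
    if f >= _CAL_F[-1]:
        return float(_CAL_C[-1])
    return float(np.interp(f, _CAL_F, _CAL_C))


def _bn_draw(parent: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols child frequencies calibrated so sister demes at F show
    realized pairwise mean per-locus F_ST of about F."""
    c = _bn_concentration(f)
    a = parent * (1.0 - c) / c
    b = (1.0 - parent) * (1.0 - c) / c
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def sim_frequencies(spec: SimSpec, rng: np.random.Generator | None = None) -> FreqTable:
    """Draw the ancestral / species-pool / deme frequency hierarchy."""
    rng = rng or np.random.default_rng(spec.seed)
    anc = rng.uniform(0.05, 0.95, size=spec.n_loci)
    pools = {name: _bn_draw(anc, f, rng) for name, f in spec.species_f.items()}
    demes: dict[str, np.ndarray] = {}
    for sp in spec.subpops:
        demes[sp.name] = _bn_draw(pools["longistaminata"], sp.f_sub, rng)
    if spec.sativa_split_f > 0:
        demes["sativa_a"] = _bn_draw(pools["sativa"], spec.sativa_split_f, rng)
        demes["sativa_b"] = _bn_draw(pools["sativa"], spec.sativa_split_f, rng)
    else:
        demes["sativa_a"] = pools["sativa"]
        demes["sativa_b"] = pools["sativa"]
    demes["barthii"] = _bn_draw(pools["barthii_glaberrima"], spec.bg_split_f, rng)
    demes["glaberrima"] = _bn_draw(pools["barthii_glaberrima"], spec.bg_split_f, rng)
    return FreqTable(ancestral=anc, pools=pools, demes=demes)


# ---------------------------------------------------------------------------
# genotype draws
# ---------------------------------------------------------------------------


def sim_individual(
    freq_rows: np.ndarray,
    q: np.ndarray,
    f_is: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One diploid genotype row from a mixture of frequency components.

    Each allele copy picks an ancestry component from ``q`` then an allele
    from that component's frequency; with probability ``f_is`` the second
    copy duplicates the first (allele and origin), producing an expected
    heterozygosity deficit of factor ``1 - f_is``.

    Returns (dosage row, realized per-component copy fractions).
    """
    K, L = freq_rows.shape
    q = np.asarray(q, dtype=float)
    cum = np.cumsum(q)
    o1 = np.searchsorted(cum, rng.random(L) * cum[-1], side="right")
    o2 = np.searchsorted(cum, rng.random(L) * cum[-1], side="right")
    a1 = (rng.random(L) < freq_rows[o1, np.arange(L)]).astype(np.int8)
    a2 = (rng.random(L) < freq_rows[o2, np.arange(L)]).astype(np.int8)
    dup = rng.random(L) < f_is
    a2 = np.where(dup, a1, a2)
    o2 = np.where(dup, o1, o2)
    dosage = (a1 + a2).astype(np.int8)
    frac = np.bincount(np.concatenate([o1, o2]), minlength=K) / (2.0 * L)
    return dosage, frac


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


class _Plant:
    """Internal diploid with per-copy alleles and species origins."""

    __slots__ = ("alleles", "origins", "maternal")

    def __init__(self, alleles: np.ndarray, origins: np.ndarray, maternal: str):
        self.alleles = alleles  # (2, L) in {0, 1}
        self.origins = origins  # (2, L) species-pool index
        self.maternal = maternal

    def gamete(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        pick = rng.integers(0, 2, size=self.alleles.shape[1])
        cols = np.arange(self.alleles.shape[1])
        return self.alleles[pick, cols], self.origins[pick, cols]


def _founder(
    species: str, freqs: FreqTable, rng: np.random.Generator, inbred: bool
) -> _Plant:
    p = freqs.pools[species if species in freqs.pools else "barthii_glaberrima"]
    L = p.shape[0]
    idx = SPECIES_POOLS.index(species if species in SPECIES_POOLS else "barthii_glaberrima")
    if inbred:
        hap = (rng.random(L) < p).astype(np.int8)
        alleles = np.stack([hap, hap.copy()])
    else:
        alleles = (rng.random((2, L)) < p).astype(np.int8)
    origins = np.full((2, L), idx, dtype=np.int8)
    return _Plant(alleles, origins, maternal=species)


def _cross(mother: _Plant, father: _Plant, rng: np.random.Generator) -> _Plant:
    am, om = mother.gamete(rng)
    af, of = father.gamete(rng)
    return _Plant(np.stack([am, af]), np.stack([om, of]), maternal=mother.maternal)


def _parse_scheme(scheme: str) -> list[str]:
    s = scheme.strip()
    if s == "F1":
        return ["F1"]
    if s == "F2":
        return ["F1", "SELF"]
    if s.startswith("BC1:"):
        return ["F1", f"BC:{s[4:]}"]
    if s.startswith("BC2:"):
        return ["F1", f"BC:{s[4:]}", f"BC:{s[4:]}"]
    if s.startswith("RIL"):
        k = int(s[3:]) if len(s) > 3 else 6
        return ["F1"] + ["SELF"] * k
    # explicit chain
    steps = s.split("-")
    if steps[0] != "F1":
        raise ValueError(f"pedigree scheme must start at F1: {scheme!r} (position 0)")
    out = ["F1"]
    for pos, tok in enumerate(steps[1:], start=1):
        if tok == "F2" or tok == "SELF":
            out.append("SELF")
        elif tok.startswith("SELF"):
            out.extend(["SELF"] * int(tok[4:]))
        elif tok.startswith("BC:"):
            out.append(tok)
        else:
            raise ValueError(f"bad pedigree token {tok!r} in {scheme!r} (position {pos})")
    return out


def sim_pedigree(
    freqs: FreqTable,
    ped: PedigreeSpec,
    rng: np.random.Generator,
) -> tuple[_Plant, dict[str, float]]:
    """Run one crossing scheme; returns the final plant and its realized
    per-species ancestry fractions."""
    other = "longistaminata" if ped.maternal != "longistaminata" else "sativa"
    mother = _founder(ped.maternal, freqs, rng, inbred=(ped.maternal != "longistaminata"))
    father = _founder(other, freqs, rng, inbred=(other != "longistaminata"))
    plant: _Plant | None = None
    for step in _parse_scheme(ped.scheme):
        if step == "F1":
            plant = _cross(mother, father, rng)
        elif step == "SELF":
            plant = _cross(plant, plant, rng)
        elif step.startswith("BC:"):
            sp = step[3:]
            recurrent = _founder(sp, freqs, rng, inbred=(sp != "longistaminata"))
            plant = _cross(plant, recurrent, rng)  # hybrid as mother: plastid kept
        else:  # pragma: no cover
            raise AssertionError(step)
    fracs = {
        name: float((plant.origins == i).mean()) for i, name in enumerate(SPECIES_POOLS)
    }
    return plant, fracs


# ---------------------------------------------------------------------------
# plastid SSRs
# ---------------------------------------------------------------------------


def sim_plastid(
    spec: SimSpec,
    lineages: list[str],
    rng: np.random.Generator,
    mutate: list[bool] | None = None,
) -> np.ndarray:
    """Stepwise-mutated maternal haplotypes, one row per lineage entry.

    ``lineages`` names each individual's maternal species; entries with
    ``mutate=False`` (hybrids) carry the species founder haplotype unchanged.
    """
    n_loci = len(next(iter(SSR_FOUNDERS.values())))
    out = np.zeros((len(lineages), n_loci), dtype=int)
    for i, species in enumerate(lineages):
        hap = np.array(SSR_FOUNDERS[species], dtype=int)
        if mutate is None or mutate[i]:
            for _ in range(rng.poisson(spec.ssr_mutation_rate)):
                locus = rng.integers(n_loci)
                hap[locus] += rng.choice((-1, 1))
        out[i] = hap
    return out


# ---------------------------------------------------------------------------
# panel assembly and emission
# ---------------------------------------------------------------------------


def _subpop_q(
    coords: tuple[float, float], spec: SimSpec
) -> np.ndarray:
    """Logistic ancestry mixing over subpop centers; pure indicator when
    ``gradient_km`` is None is handled by the caller."""
    d = np.array([haversine(coords, sp.center) for sp in spec.subpops])
    w = np.exp(-d / spec.gradient_km)
    return w / w.sum()


def simulate_panel(spec: SimSpec) -> tuple[SnpMatrix, SsrTable, SimTruth]:
    """Generate the full panel in memory (genotypes, plastid SSRs, truth)."""
    rng = np.random.default_rng(spec.seed)
    freqs = sim_frequencies(spec, rng)
    L = spec.n_loci

    # mixture components for wild individuals: subpops + sativa pool
    wild_rows = np.stack(
        [freqs.demes[sp.name] for sp in spec.subpops] + [freqs.pools["sativa"]]
    )
    n_sub = len(spec.subpops)

    individuals: list[IndividualMeta] = []
    calls: list[np.ndarray] = []
    truth_rows: list[dict] = []
    lineages: list[str] = []
    mutate: list[bool] = []
    locus_origins: dict[str, np.ndarray] = {}

    # -- wild subpopulations (two individuals per grid site) ------------
    site_coords: dict[str, list[tuple[float, float]]] = {}
    for sp in spec.subpops:
        n_sites = (sp.n + 1) // 2
        side = max(int(math.ceil(math.sqrt(n_sites))), 1)
        pts = []
        for r in range(side):
            for c in range(side):
                if len(pts) >= n_sites:
                    break
                lat = sp.center[0] + (r - side / 2) * 2.0 + rng.uniform(-1, 1) * spec.coord_jitter
                lon = sp.center[1] + (c - side / 2) * 2.0 + rng.uniform(-1, 1) * spec.coord_jitter
                pts.append((round(lat, 4), round(lon, 4)))
        site_coords[sp.name] = pts
        for i in range(sp.n):
            coords = pts[i // 2]
            if spec.gradient_km is None:
                q_sub = np.eye(n_sub)[[s.name for s in spec.subpops].index(sp.name)]
            else:
                q_sub = _subpop_q(coords, spec)
            a = sp.ancient_sativa
            q = np.concatenate([q_sub * (1.0 - a), [a]])
            dosage, frac = sim_individual(wild_rows, q, sp.f_is, rng)
            uid = f"{sp.name[:2].upper()}{i + 1:03d}"
            individuals.append(
                IndividualMeta(
                    id=uid,
                    species_label="longistaminata",
                    accession=f"{sp.name[:2].upper()}-ACC{i // 2 + 1:03d}",
                    latitude=coords[0],
                    longitude=coords[1],
                )
            )
            calls.append(dosage)
            lineages.append("longistaminata")
            mutate.append(True)
            row = {
                "id": uid,
                "species": "longistaminata",
                "subpop": sp.name,
                "pedigree": "",
                "maternal": "longistaminata",
                "lat": coords[0],
                "lon": coords[1],
                "q_longistaminata": 1.0 - a,
                "q_sativa": a,
                "q_barthii_glaberrima": 0.0,
            }
            for k, s2 in enumerate(spec.subpops):
                row[f"q_{s2.name}"] = q[k]
            truth_rows.append(row)

    # -- outgroup species ------------------------------------------------
    outgroup_demes = {
        "sativa": ["sativa_a", "sativa_b"],
        "barthii_glaberrima": ["barthii", "glaberrima"],
    }
    for species, n in spec.outgroups.items():
        demes = outgroup_demes[species]
        for i in range(n):
            deme = demes[i % len(demes)]
            p = freqs.demes[deme][None, :]
            dosage, _ = sim_individual(p, np.array([1.0]), spec.outgroup_f_is, rng)
            uid = f"{deme[:3].upper()}{i + 1:03d}"
            label = "sativa" if species == "sativa" else deme
            individuals.append(
                IndividualMeta(id=uid, species_label=label, accession=f"OG-{uid}")
            )
            calls.append(dosage)
            lineages.append(species)
            mutate.append(True)
            truth_rows.append(
                {
                    "id": uid,
                    "species": species,
                    "subpop": deme,
                    "pedigree": "",
                    "maternal": species,
                    "lat": np.nan,
                    "lon": np.nan,
                    "q_longistaminata": 0.0,
                    "q_sativa": 1.0 if species == "sativa" else 0.0,
                    "q_barthii_glaberrima": 0.0 if species == "sativa" else 1.0,
                    **{f"q_{s2.name}": 0.0 for s2 in spec.subpops},
                }
            )

    # -- pedigreed hybrids ----------------------------------------------
    ped_counter: dict[str, int] = {}
    for ped in spec.pedigrees:
        for _ in range(ped.count):
            plant, fracs = sim_pedigree(freqs, ped, rng)
            k = ped_counter.get(ped.scheme, 0) + 1
            ped_counter[ped.scheme] = k
            uid = f"{'FLD' if ped.label != 'control_hybrid' else 'CTL'}_{ped.scheme.replace(':', '')}_{k}"
            if ped.at_subpop is not None:
                pts = site_coords[ped.at_subpop]
                coords = pts[int(rng.integers(len(pts)))]
            else:
                coords = (None, None)
            individuals.append(
                IndividualMeta(
                    id=uid,
                    species_label=ped.label,
                    accession=f"PED-{uid}",
                    latitude=coords[0],
                    longitude=coords[1],
                )
            )
            calls.append(plant.alleles.sum(axis=0).astype(np.int8))
            lineages.append(ped.maternal)
            mutate.append(False)
            locus_origins[uid] = plant.origins.copy()
            truth_rows.append(
                {
                    "id": uid,
                    "species": ped.label,
                    "subpop": "",
                    "pedigree": ped.scheme,
                    "maternal": ped.maternal,
                    "lat": coords[0] if coords[0] is not None else np.nan,
                    "lon": coords[1] if coords[1] is not None else np.nan,
                    "q_longistaminata": fracs["longistaminata"],
                    "q_sativa": fracs["sativa"],
                    "q_barthii_glaberrima": fracs["barthii_glaberrima"],
                    **{f"q_{s2.name}": np.nan for s2 in spec.subpops},
                }
            )

    calls_arr = np.stack(calls)
    n_ind = calls_arr.shape[0]

    # -- observation model: missingness, then read depths ----------------
    miss = rng.random(calls_arr.shape) < spec.missing_rate
    calls_arr = np.where(miss, MISSING, calls_arr).astype(np.int8)

    k_nb = spec.depth_overdispersion
    p_nb = k_nb / (k_nb + spec.depth_mean)
    total = rng.negative_binomial(k_nb, p_nb, size=calls_arr.shape)
    total = np.where(calls_arr == MISSING, 0, total)
    alt_p = np.where(calls_arr == MISSING, 0.0, np.maximum(calls_arr, 0) / 2.0)
    alt_d = rng.binomial(total, alt_p)
    depths = np.stack([total - alt_d, alt_d], axis=2)

    # -- site coordinates along chromosomes ------------------------------
    n_chrom = 4
    per = (L + n_chrom - 1) // n_chrom
    sites = []
    for j in range(L):
        chrom = f"{j // per + 1}"
        if j % per == 0:
            pos = 1
        else:
            pos += int(rng.integers(40, 250))
        sites.append(SiteMeta(chrom=chrom, pos=pos, ref="A", alt="G"))

    m = SnpMatrix(individuals=individuals, sites=sites, calls=calls_arr, depths=depths)
    ssr = SsrTable(
        individuals=[ind.id for ind in individuals],
        loci=[f"cpSSR{i + 1}" for i in range(7)],
        alleles=sim_plastid(spec, lineages, rng, mutate),
    )
    truth = SimTruth(
        frame=pd.DataFrame(truth_rows).set_index("id"), locus_origins=locus_origins
    )
    return m, ssr, truth


def two_cluster_spec(seed: int, n_loci: int = 500) -> SimSpec:
    """Panel design with one wild-species cluster and one pooled outgroup
    cluster: three wild subpops (F_sub = 0.02) plus a single domesticated
    outgroup pool at species divergence 0.30, ~120 individuals.  The design
    behind the all-species delta-K check (expected optimum: K = 2).
    """
    return SimSpec(
        seed=seed,
        n_loci=n_loci,
        subpops=(
            SubpopSpec("Northwestern", (14.0, -5.0), n=28, f_sub=0.02, f_is=0.28),
            SubpopSpec("PanAfrica", (0.0, 20.0), n=28, f_sub=0.02, f_is=0.29),
            SubpopSpec("Southern", (-20.0, 35.0), n=24, f_sub=0.02, f_is=0.44),
        ),
        outgroups={"sativa": 40},
        sativa_split_f=0.0,
        pedigrees=(),
    )


def six_cluster_spec(seed: int, n_loci: int = 2000) -> SimSpec:
    """Six-cluster panel design for the DAPC/BIC check: three wild subpops
    (F_sub = 0.05), two domesticated sativa demes (split 0.10), and one
    barthii-glaberrima outgroup pair drawn from a common pool.
    """
    return SimSpec(
        seed=seed,
        n_loci=n_loci,
        subpops=(
            SubpopSpec("Northwestern", (14.0, -5.0), n=24, f_sub=0.05, f_is=0.28),
            SubpopSpec("PanAfrica", (0.0, 20.0), n=24, f_sub=0.05, f_is=0.29),
            SubpopSpec("Southern", (-20.0, 35.0), n=24, f_sub=0.05, f_is=0.44),
        ),
        outgroups={"sativa": 24, "barthii_glaberrima": 16},
        sativa_split_f=0.10,
        bg_split_f=1e-4,
        gradient_km=None,  # crisp subpop membership for the clustering design
        pedigrees=(),
    )


def emit(spec: SimSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the panel to files (VCF, metadata CSV, SSR CSV, truth TSV).

    Byte-identical across runs with the same spec and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, ssr, truth = simulate_panel(spec)
    paths = {
        "vcf": outdir / "panel.vcf",
        "metadata": outdir / "metadata.csv",
        "ssr": outdir / "plastid_ssr.csv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(m, paths["vcf"])
    write_metadata_csv(m.individuals, paths["metadata"])
    write_ssr_csv(ssr, paths["ssr"])
    truth.frame.to_csv(paths["truth"], sep="\t", float_format="%.6f")
    return paths
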