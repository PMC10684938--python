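"""Multi-pass orchestration: all-species structure, hybrid screening,
within-species reanalysis, and supervised ancestry profiling.

Pass 1 filters the panel, runs replicate unsupervised admixture chains over a
K grid with Evanno delta-K selection, runs DAPC, and screens for putative
interspecific hybrids against RIL-calibrated thresholds.  Pass 2 re-analyses
only the sub-threshold conspecific individuals with site statistics
recomputed on the subset.  The supervised pass fixes reference individuals
of each species group and profiles everyone else's ancestry at K = 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import AdmixtureModel, AncestryFit, EvannoResult, PopPrior, RunConfig, evanno
from .dapc import ClusterSearch, find_clusters, fit_assign, n_pcs_for_clustering, run_pca
from .filters import FilterParams, filter_individuals, filter_sites
from .haplonet import collapse_haplotypes
from .hybrids import AncestryProfile, HybridThresholds, calibrate, classify_panel
from .snp import MISSING, SnpMatrix, SsrTable

logger = logging.getLogger(__name__)

GROUP_ORDER = ("sativa", "longistaminata", "barthii_glaberrima")


@dataclass
class PipelineConfig:
    filter_params: FilterParams = field(default_factory=FilterParams)
    run_config: RunConfig = field(default_factory=lambda: RunConfig.reduced(K_range=tuple(range(1, 6))))
    k_max_dapc: int = 9
    n_start: int = 50
    pass2_cutoff: float = 0.045  # exclusion rule for the within-species pass
    ref_cutoff: float = 0.01     # max admixture for supervised reference individuals
    seed: int = 0
    method: str = "gibbs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config whose top-level keys mirror the dataclass fields;
        ``filter_params`` and ``run_config`` are nested mappings."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "filter_params" in kw:
            kw["filter_params"] = FilterParams(**kw["filter_params"])
        if "run_config" in kw:
            rc = dict(kw["run_config"])
            if "K_range" in rc:
                rc["K_range"] = tuple(rc["K_range"])
            kw["run_config"] = RunConfig(**rc)
        return cls(**kw)


@dataclass
class Pass1Result:
    matrix: SnpMatrix
    lnp_by_k: dict[int, list[float]]
    evanno: EvannoResult
    fits: dict[int, list[AncestryFit]]
    cluster_search: ClusterSearch
    dapc_assignments: pd.Series
    admixture: pd.Series          # per-id outgroup admixture from the K=2-style fit
    thresholds: HybridThresholds
    hybrid_report: pd.DataFrame   # longistaminata-labeled entries only


@dataclass
class Pass2Result:
    matrix: SnpMatrix
    lnp_by_k: dict[int, list[float]]
    evanno: EvannoResult
    cluster_search: ClusterSearch
    dapc_assignments: pd.Series


def _wild_cluster(fit: AncestryFit, m: SnpMatrix) -> int:
    """Cluster carrying the wild species: max mean Q among longistaminata."""
    wild = np.array([ind.species_label == "longistaminata" for ind in m.individuals])
    if not wild.any():
        raise ValueError("no longistaminata-labeled individuals in panel")
    return int(fit.Q[wild].mean(axis=0).argmax())


def outgroup_admixture(fit: AncestryFit, m: SnpMatrix) -> pd.Series:
    """Per-individual total ancestry outside the wild-species cluster."""
    k = _wild_cluster(fit, m)
    return pd.Series(1.0 - fit.Q[:, k], index=m.ids, name="outgroup_admixture")


def run_pass1(m: SnpMatrix, cfg: PipelineConfig | None = None) -> Pass1Result:
    """All-species pass: filter, admixture K grid + Evanno, DAPC, hybrid screen."""
    cfg = cfg or PipelineConfig()
    log: list = []
    filtered = filter_individuals(m, cfg.filter_params, log)
    filtered = filter_sites(filtered, cfg.filter_params, log)
    logger.info("pass1 filter: %d -> %d individuals, %d -> %d sites",
                m.n_individuals, filtered.n_individuals, m.n_sites, filtered.n_sites)

    model = AdmixtureModel(filtered)
    lnp, fits = model.fit_k_grid(cfg.run_config, method=cfg.method)
    ev = evanno(lnp)

    pca = run_pca(filtered)
    n_pcs = n_pcs_for_clustering(filtered.n_individuals)
    search = find_clusters(
        pca.scores[:, :n_pcs], K_max=min(cfg.k_max_dapc, filtered.n_individuals - 1),
        n_start=cfg.n_start, seed=cfg.seed,
    )
    labels = search.best_assignment()
    if search.optimal_K >= 2:
        dapc = fit_assign(pca.scores[:, :n_pcs], labels)
        assignments = pd.Series(dapc.assignments, index=filtered.ids, name="dapc_group")
    else:
        assignments = pd.Series(labels, index=filtered.ids, name="dapc_group")

    # hybrid screen from the K=2-style structure fit (best replicate at the
    # Evanno optimum, or K=2 when the grid contains it)
    k_screen = 2 if 2 in lnp else ev.optimal_K
    best = fits[k_screen][int(np.argmax(lnp[k_screen]))]
    admix = outgroup_admixture(best, filtered)

    # calibration uses the controls' minority ancestry fraction (the published
    # band derives from the minimum admixture seen in backcross-derived RILs)
    controls = [
        min(admix[ind.id], 1.0 - admix[ind.id])
        for ind in filtered.individuals
        if ind.species_label == "control_hybrid" and 0.0 < admix[ind.id] < 1.0
    ]
    thresholds = calibrate(controls) if controls else HybridThresholds()

    rows = []
    for ind in filtered.individuals:
        if ind.species_label != "longistaminata":
            continue
        a = float(admix[ind.id])
        rows.append(
            {
                "entry": ind.id,
                "outgroup_admixture": a,
                "status": "putative_hybrid"
                if thresholds.lower <= a <= thresholds.upper
                else "pure",
            }
        )
    report = pd.DataFrame(rows, columns=["entry", "outgroup_admixture", "status"])
    report = report.set_index("entry") if len(rows) else report
    hybrids_only = report[report["status"] == "putative_hybrid"] if len(rows) else report

    return Pass1Result(
        matrix=filtered,
        lnp_by_k=lnp,
        evanno=ev,
        fits=fits,
        cluster_search=search,
        dapc_assignments=assignments,
        admixture=admix,
        thresholds=thresholds,
        hybrid_report=hybrids_only,
    )


def run_pass2(pass1: Pass1Result, cfg: PipelineConfig | None = None) -> Pass2Result:
    """Within-species pass on sub-threshold conspecific individuals."""
    cfg = cfg or PipelineConfig()
    m = pass1.matrix
    keep = [
        ind.id
        for ind in m.individuals
        if ind.species_label == "longistaminata"
        and pass1.admixture[ind.id] < cfg.pass2_cutoff
    ]
    if len(keep) < 3:
        raise ValueError("pass-2 subset too small (< 3 individuals)")
    subset = m.subset_ids(keep)
    subset = filter_sites(subset, cfg.filter_params)  # MAF/presence recomputed

    model = AdmixtureModel(subset)
    lnp, _ = model.fit_k_grid(cfg.run_config, method=cfg.method)
    ev = evanno(lnp)

    pca = run_pca(subset)
    n_pcs = n_pcs_for_clustering(subset.n_individuals)
    search = find_clusters(
        pca.scores[:, :n_pcs], K_max=min(cfg.k_max_dapc, subset.n_individuals - 1),
        n_start=cfg.n_start, seed=cfg.seed,
    )
    labels = search.best_assignment()
    if search.optimal_K >= 2:
        dapc = fit_assign(pca.scores[:, :n_pcs], labels)
        assignments = pd.Series(dapc.assignments, index=subset.ids, name="dapc_group")
    else:
        assignments = pd.Series(labels, index=subset.ids, name="dapc_group")
    return Pass2Result(
        matrix=subset,
        lnp_by_k=lnp,
        evanno=ev,
        cluster_search=search,
        dapc_assignments=assignments,
    )


def plastid_groups(ssr: SsrTable, m: SnpMatrix, admixture: pd.Series | None = None) -> dict[str, str]:
    """Assign each individual a plastid species group.

    Haplotypes are collapsed over complete cases; each haplotype takes the
    majority species among its non-hybrid carriers (species groups pooled as
    sativa / longistaminata / barthii_glaberrima), and every carrier inherits
    that group.
    """
    complete = ssr.complete_cases()
    species = {ind.id: ind.species_label for ind in m.individuals}

    def pool(label: str | None) -> str | None:
        if label in ("barthii", "glaberrima"):
            return "barthii_glaberrima"
        return label

    anchors = {
        i: pool(species[i])
        for i in complete.individuals
        if species.get(i) in ("longistaminata", "sativa", "barthii", "glaberrima")
        and (admixture is None or abs(admixture.get(i, 0.0)) < 0.1)
    }
    nodes = collapse_haplotypes(complete, {k: v for k, v in anchors.items() if v})
    out: dict[str, str] = {}
    for node in nodes:
        votes = {g: c for g, c in node.composition.items() if g != "unknown"}
        if not votes:
            continue
        group = max(sorted(votes), key=lambda g: votes[g])
        for carrier in node.carriers:
            out[carrier] = group
    return out


def run_supervised(
    m: SnpMatrix,
    cfg: PipelineConfig | None = None,
    pass1: Pass1Result | None = None,
    ssr: SsrTable | None = None,
) -> tuple[list[AncestryProfile], pd.DataFrame]:
    """Supervised K = 3 profiling with replicate-averaged Q values.

    Reference (flagged) individuals are those of each species group whose
    pass-1 outgroup admixture is below ``ref_cutoff`` (all labeled
    conspecifics when no pass-1 result is given).  Returns the per-entry
    profiles and a Table-1-style classification report.
    """
    cfg = cfg or PipelineConfig()
    labels = np.full(m.n_individuals, -1, dtype=int)
    group_of = {"sativa": 0, "longistaminata": 1, "barthii": 2, "glaberrima": 2}
    for i, ind in enumerate(m.individuals):
        g = group_of.get(ind.species_label)
        if g is None:
            continue
        if pass1 is not None and ind.species_label == "longistaminata":
            if pass1.admixture.get(ind.id, 1.0) >= cfg.ref_cutoff:
                continue
        labels[i] = g
    for g in range(3):
        if not (labels == g).any():
            raise ValueError(f"no reference individuals for group {GROUP_ORDER[g]}")

    prior = PopPrior.from_labels(labels)
    model = AdmixtureModel(m)
    reps = []
    for c in range(cfg.run_config.n_chains):
        fit = model.fit_supervised(
            3, prior, config=cfg.run_config, method=cfg.method,
            seed=cfg.run_config.seed + 31 * c,
        )
        reps.append(fit.Q)
    Q = np.mean(reps, axis=0)

    plastid = plastid_groups(ssr, m) if ssr is not None else {}
    profiles = []
    for i, ind in enumerate(m.individuals):
        q = Q[i] / Q[i].sum()
        profiles.append(
            AncestryProfile(
                entry=ind.id,
                q_sativa=float(q[0]),
                q_longistaminata=float(q[1]),
                q_barthii_glaberrima=float(q[2]),
                species_label=ind.species_label,
                plastid_group=plastid.get(ind.id),
            )
        )
    thresholds = pass1.thresholds if pass1 is not None else HybridThresholds()
    report = classify_panel(profiles, thresholds)
    return profiles, report


def compare_assignments(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Cross-tabulate two group assignments after canonical label matching.

    Labels of ``b`` are mapped onto ``a``'s by greedy maximum agreement on
    the shared individuals; returns the individuals whose (mapped) group
    changed, as a DataFrame with columns ``from`` and ``to``.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("assignments share no individuals")
    a = a.loc[shared]
    b = b.loc[shared]
    tab = pd.crosstab(a, b)
    mapping: dict = {}
    used_rows: set = set()
    flat = tab.stack().sort_values(ascending=False)
    for (ra, cb), _ in flat.items():
        if cb in mapping or ra in used_rows:
            continue
        mapping[cb] = ra
        used_rows.add(ra)
    b_mapped = b.map(lambda x: mapping.get(x, x))
    moved = shared[(a != b_mapped).to_numpy()]
    return pd.DataFrame({"from": a.loc[moved], "to": b_mapped.loc[moved]})
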