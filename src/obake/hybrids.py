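"""RIL-calibrated interspecific-hybrid classification.

An entry's outgroup admixture is its total non-conspecific supervised
ancestry (1 - Q of its own species).  Entries whose admixture falls inside a
symmetric band calibrated from control recombinant inbred lines (defaults
4.4%-95.6%) are putative interspecific hybrids; the minority-parent ancestry
fraction then places them in a generation band (F1/F2 ~ 0.5, BC1 ~ 0.25,
BC2 ~ 0.125, else advanced), and the maternally inherited plastid haplotype
identifies the maternal parent.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENERATION_EXPECTATIONS = {"F1_F2": 0.5, "BC1": 0.25, "BC2": 0.125}


@dataclass(frozen=True)
class AncestryProfile:
    """Supervised ancestry of one entry (averaged over replicates)."""

    entry: str
    q_sativa: float
    q_longistaminata: float
    q_barthii_glaberrima: float
    species_label: str = "longistaminata"
    plastid_group: str | None = None  # longistaminata | sativa | barthii | None
    origin: str = ""

    def __post_init__(self) -> None:
        total = self.q_sativa + self.q_longistaminata + self.q_barthii_glaberrima
        if not math.isclose(total, 1.0, abs_tol=0.02):
            raise ValueError(f"{self.entry}: Q components sum to {total:.3f}, not 1 +/- 0.02")

    @property
    def q_triple(self) -> tuple[float, float, float]:
        return (self.q_sativa, self.q_longistaminata, self.q_barthii_glaberrima)


@dataclass(frozen=True)
class HybridThresholds:
    """Symmetric admixture band bounding putative hybrids."""

    lower: float = 0.044
    upper: float = 0.956
    calibration: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError("need 0 < lower < upper < 1")
        if abs((self.lower + self.upper) - 1.0) > 1e-9:
            raise ValueError("band must be symmetric: lower + upper = 1")


@dataclass
class HybridCall:
    """Classification of one entry."""

    entry: str
    status: str  # pure | putative_hybrid
    outgroup_admixture: float
    minority_fraction: float | None = None
    generation_band: str = "none"  # F1_F2 | BC1 | BC2 | advanced | none
    direction: str = "none"  # into_sativa | into_longistaminata | balanced | none
    maternal_parent: str | None = None
    cytonuclear_consistent: bool | None = None
    borderline: bool = False  # admixture in [0.044, 0.045): threshold-definition gap


def calibrate(controls: list[float] | None = None) -> HybridThresholds:
    """Thresholds from control-hybrid admixture values.

    ``lower`` is the minimum control rounded down to 3 decimals minus one
    grid step (0.001), so the band always contains the minimum control;
    ``upper = 1 - lower``.  Without controls the published defaults
    (0.044, 0.956) are used.
    """
    if not controls:
        return HybridThresholds()
    for c in controls:
        if not 0.0 < c < 1.0:
            raise ValueError(f"control admixture {c} outside (0, 1)")
    lower = math.floor(min(controls) * 1000.0) / 1000.0 - 0.001
    return HybridThresholds(lower=lower, upper=1.0 - lower, calibration=tuple(controls))


def generation_band(minority_fraction: float, delta: float = 0.06) -> str:
    """Generation band from the minority-parent ancestry fraction."""
    for band, expected in GENERATION_EXPECTATIONS.items():
        if abs(minority_fraction - expected) <= delta:
            return band
    return "advanced"


def classify(
    p: AncestryProfile,
    t: HybridThresholds | None = None,
    delta: float = 0.06,
    sativa_only: bool = False,
) -> HybridCall:
    """Classify one entry as pure or putative interspecific hybrid.

    Outgroup admixture is total non-conspecific ancestry (sativa-labeled
    entries use 1 - Q_sativa, all others 1 - Q_longistaminata); with
    ``sativa_only`` it is restricted to the Q_sativa component for
    longistaminata entries.
    """
    t = t or HybridThresholds()
    if p.species_label == "sativa":
        admix = 1.0 - p.q_sativa
    elif sativa_only:
        admix = p.q_sativa
    else:
        admix = 1.0 - p.q_longistaminata
    admix = min(max(admix, 0.0), 1.0)

    if not (t.lower <= admix <= t.upper):
        return HybridCall(
            entry=p.entry,
            status="pure",
            outgroup_admixture=admix,
            maternal_parent=p.plastid_group,
        )

    if p.q_sativa > p.q_longistaminata:
        direction = "into_sativa"
    elif p.q_longistaminata > p.q_sativa:
        direction = "into_longistaminata"
    else:
        direction = "balanced"
    # minority-parent fraction from the total outgroup admixture, so the
    # generation band is invariant to permuting the non-focal components
    minority = min(admix, 1.0 - admix)
    maternal, consistent = cytonuclear_check(p)
    return HybridCall(
        entry=p.entry,
        status="putative_hybrid",
        outgroup_admixture=admix,
        minority_fraction=minority,
        generation_band=generation_band(minority, delta),
        direction=direction,
        maternal_parent=maternal,
        cytonuclear_consistent=consistent,
        borderline=0.044 <= admix < 0.045,
    )


def cytonuclear_check(p: AncestryProfile) -> tuple[str | None, bool | None]:
    """Maternal parent from the plastid haplotype and its consistency with
    the nuclear ancestry (maternal species must contribute nuclear ancestry).
    """
    if p.plastid_group is None:
        return None, None
    nuclear = {
        "longistaminata": p.q_longistaminata,
        "sativa": p.q_sativa,
        "barthii": p.q_barthii_glaberrima,
        "glaberrima": p.q_barthii_glaberrima,
    }
    component = nuclear.get(p.plastid_group, 0.0)
    return p.plastid_group, bool(component > 0.0)


def classify_panel(
    profiles: list[AncestryProfile],
    t: HybridThresholds | None = None,
    delta: float = 0.06,
) -> pd.DataFrame:
    """Table-style classification report for a panel of entries."""
    rows = []
    for p in profiles:
        call = classify(p, t, delta)
        rows.append(
            {
                "entry": p.entry,
                "q_sativa": p.q_sativa,
                "q_longistaminata": p.q_longistaminata,
                "q_barthii_glaberrima": p.q_barthii_glaberrima,
                "origin": p.origin,
                "status": call.status,
                "outgroup_admixture": call.outgroup_admixture,
                "generation_band": call.generation_band,
                "direction": call.direction,
                "maternal_parent": call.maternal_parent,
                "borderline": call.borderline,
            }
        )
    return pd.DataFrame(rows).set_index("entry")


def low_level_admixture_summary(
    profiles: list[AncestryProfile],
    grouping: dict[str, str],
    t: HybridThresholds | None = None,
) -> pd.DataFrame:
    """Per-group mean/min/max of the outgroup ancestry components among
    sub-threshold (status pure) individuals — the ancient-introgression
    signal summary.
    """
    t = t or HybridThresholds()
    by_group: dict[str, list[AncestryProfile]] = defaultdict(list)
    for p in profiles:
        if classify(p, t).status != "pure":
            continue
        g = grouping.get(p.entry)
        if g is not None:
            by_group[g].append(p)

    rows = []
    for g in sorted(by_group):
        members = by_group[g]
        qs = np.array([p.q_sativa for p in members])
        qb = np.array([p.q_barthii_glaberrima for p in members])
        rows.append(
            {
                "group": g,
                "n": len(members),
                "sativa_mean": qs.mean(),
                "sativa_min": qs.min(),
                "sativa_max": qs.max(),
                "barthii_glaberrima_mean": qb.mean(),
                "barthii_glaberrima_min": qb.min(),
                "barthii_glaberrima_max": qb.max(),
            }
        )
    return pd.DataFrame(rows).set_index("group")
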