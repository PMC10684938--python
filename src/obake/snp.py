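"""Core genotype containers: nuclear SNP matrices and plastid SSR tables.

The :class:`SnpMatrix` is the substrate of every nuclear analysis in the
package: an individuals x sites matrix of alt-allele dosages in {0, 1, 2}
with ``MISSING`` (-1) for no-calls, optional per-call allelic depths, and
per-site/per-individual metadata.  Plastid microsatellite genotypes (haploid,
one integer fragment size per locus) live in :class:`SsrTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing call.  Distinct from 0 (homozygous ref).
MISSING: int = -1

SPECIES_LABELS = (
    "longistaminata",
    "sativa",
    "barthii",
    "glaberrima",
    "control_hybrid",
    "unknown",
)


@dataclass(frozen=True)
class IndividualMeta:
    """Identity and provenance of one sampled plant."""

    id: str
    species_label: str = "unknown"
    accession: str = ""
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.species_label not in SPECIES_LABELS:
            raise ValueError(f"unknown species label {self.species_label!r}")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")

    @property
    def has_coordinates(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class SiteMeta:
    """One variant site: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class SnpMatrix:
    """Individuals x sites dosage matrix of biallelic SNP calls.

    Parameters
    ----------
    individuals
        Row metadata, one entry per matrix row; ids must be unique.
    sites
        Column metadata; positions must be sorted within each chromosome.
    calls
        ``(n, L)`` int8 array of alt-allele dosages; ``MISSING`` marks no-calls.
    depths
        Optional ``(n, L, 2)`` array of (ref_depth, alt_depth) read counts.
    genotypes
        Optional ``(n, L, 2)`` allele-index array retaining multi-allelic
        calls (-1 = missing) until top-two-allele reduction; ``site_alleles``
        holds the full allele list per site when present.
    """

    individuals: list[IndividualMeta]
    sites: list[SiteMeta]
    calls: np.ndarray
    depths: np.ndarray | None = None
    genotypes: np.ndarray | None = None
    site_alleles: list[tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated individual ids")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.calls.shape + (2,):
                raise ValueError("depths shape must be calls shape + (2,)")

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def present(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- subsetting -----------------------------------------------------

    def take_individuals(self, index: Sequence[int]) -> "SnpMatrix":
        index = np.asarray(index, dtype=int)
        return SnpMatrix(
            individuals=[self.individuals[i] for i in index],
            sites=list(self.sites),
            calls=self.calls[index].copy(),
            depths=None if self.depths is None else self.depths[index].copy(),
            genotypes=None if self.genotypes is None else self.genotypes[index].copy(),
            site_alleles=None if self.site_alleles is None else list(self.site_alleles),
        )

    def take_sites(self, index: Sequence[int]) -> "SnpMatrix":
        index = np.asarray(index, dtype=int)
        return SnpMatrix(
            individuals=list(self.individuals),
            sites=[self.sites[j] for j in index],
            calls=self.calls[:, index].copy(),
            depths=None if self.depths is None else self.depths[:, index].copy(),
            genotypes=None if self.genotypes is None else self.genotypes[:, index].copy(),
            site_alleles=(
                None
                if self.site_alleles is None
                else [self.site_alleles[j] for j in index]
            ),
        )

    def subset_ids(self, keep: Sequence[str]) -> "SnpMatrix":
        keep_set = set(keep)
        idx = [i for i, ind in enumerate(self.individuals) if ind.id in keep_set]
        missing = keep_set - {self.individuals[i].id for i in idx}
        if missing:
            raise KeyError(f"ids not in matrix: {sorted(missing)}")
        return self.take_individuals(idx)

    # -- summaries ------------------------------------------------------

    def site_missingness(self) -> np.ndarray:
        return 1.0 - self.present().mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return 1.0 - self.present().mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (NaN if none)."""
        present = self.present()
        dosage = np.where(present, self.calls, 0).astype(float)
        n = present.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dosage.sum(axis=0) / (2.0 * n), np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Dosage matrix as a DataFrame (NaN for missing); ids x ``chrom:pos``."""
        cols = [f"{s.chrom}:{s.pos}" for s in self.sites]
        data = self.calls.astype(float)
        data[self.calls == MISSING] = np.nan
        return pd.DataFrame(data, index=self.ids, columns=cols)


@dataclass
class SsrTable:
    """Haploid plastid microsatellite genotypes: one allele size per locus."""

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, n_loci) int, MISSING for no-calls

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("allele table shape mismatch")
        valid = (self.alleles > 0) | (self.alleles == MISSING)
        if not valid.all():
            raise ValueError("allele sizes must be positive integers or MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def complete_cases(self) -> "SsrTable":
        """Drop individuals with any missing locus (network input rule)."""
        keep = (self.alleles != MISSING).all(axis=1)
        return SsrTable(
            individuals=[i for i, k in zip(self.individuals, keep) if k],
            loci=list(self.loci),
            alleles=self.alleles[keep].copy(),
        )


@dataclass
class SiteFreqMatrix:
    """Collection sites x loci alt-allele frequencies (pooled genotypes).

    ``freqs`` is NaN where a locus has no calls at a site; ``n`` counts the
    diploid individuals pooled into each site.
    """

    site_ids: list[str]
    latitudes: np.ndarray
    longitudes: np.ndarray
    n: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.freqs.shape[0] != len(self.site_ids):
            raise ValueError("frequency rows must match site ids")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)
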