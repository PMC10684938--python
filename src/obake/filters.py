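"""The post-calling SNP filter cascade and genotype pooling utilities.

The cascade mirrors a RAD-seq quality pipeline for a mixed-species diploid
panel, applied in a fixed order:

1. top-two-allele reduction per record (calls carrying rarer alleles become
   missing);
2. per-call allelic-depth masking (ref+alt depth outside ``[depth_min,
   depth_max]`` masks the call);
3. site-level drops: heterozygous fraction above ``max_het_fraction``, minor
   allele frequency below ``maf_min``, non-missing fraction below
   ``site_presence_min``.

Individual-level missingness filtering and 100-bp positional thinning are
separate operations so each analysis subset can recompute site statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .snp import MISSING, SiteFreqMatrix, SiteMeta, SnpMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the filter cascade.

    Defaults follow the RAD-seq protocol this package models: heterozygous
    fraction cap 0.5, allelic depths 7-400, MAF 0.01, site presence 66%,
    individual missingness cap 40%, 100-bp thinning for spatial analyses.
    """

    max_het_fraction: float = 0.5
    depth_min: int = 7
    depth_max: int = 400
    maf_min: float = 0.01
    site_presence_min: float = 0.66
    indiv_missing_max: float = 0.40
    thin_bp: int | None = 100

    def __post_init__(self) -> None:
        for name in ("max_het_fraction", "maf_min", "site_presence_min", "indiv_missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min > depth_max")


def _site_label(s: SiteMeta) -> str:
    return f"{s.chrom}:{s.pos}"


def _reduce_top_two(m: SnpMatrix) -> SnpMatrix:
    """Retain the two most common alleles per record; other calls -> missing.

    No-op for matrices without raw genotype indices (already biallelic).
    Ties in allele counts are broken toward the lower allele index.  The ref
    designation is kept when the reference allele survives; otherwise the more
    common surviving allele becomes ref.
    """
    if m.genotypes is None or m.site_alleles is None:
        return m
    n, L, _ = m.genotypes.shape
    calls = m.calls.copy()
    sites = list(m.sites)
    for j in range(L):
        n_alleles = len(m.site_alleles[j])
        if n_alleles <= 2:
            continue
        g = m.genotypes[:, j, :]
        ok = (g != MISSING).all(axis=1)
        counts = np.bincount(g[ok].ravel(), minlength=n_alleles)
        top2 = np.argsort(-counts, kind="stable")[:2]  # stable => lower index wins ties
        if counts[top2[1]] == 0:
            top2 = top2[:1]
        allowed = set(int(a) for a in top2)
        if 0 in allowed:
            ref_idx = 0
            alt_candidates = [a for a in allowed if a != 0]
            alt_idx = alt_candidates[0] if alt_candidates else None
        else:
            ref_idx = int(top2[0])
            alt_idx = int(top2[1]) if len(top2) > 1 else None
        in_top = ok & np.isin(g, list(allowed)).all(axis=1)
        new_calls = np.full(n, MISSING, dtype=np.int8)
        if alt_idx is not None:
            new_calls[in_top] = (g[in_top] == alt_idx).sum(axis=1)
        else:
            new_calls[in_top] = 0
        calls[:, j] = new_calls
        alleles = m.site_alleles[j]
        sites[j] = SiteMeta(
            chrom=sites[j].chrom,
            pos=sites[j].pos,
            ref=alleles[ref_idx],
            alt=alleles[alt_idx] if alt_idx is not None else ".",
        )
    return SnpMatrix(
        individuals=list(m.individuals),
        sites=sites,
        calls=calls,
        depths=None if m.depths is None else m.depths.copy(),
        genotypes=None,  # reduction complete; matrix is now strictly biallelic
        site_alleles=None,
    )


def filter_sites(
    m: SnpMatrix, p: FilterParams | None = None, log: list | None = None
) -> SnpMatrix:
    """Apply the call- and site-level filter cascade; returns a new matrix.

    ``log`` (if given) accumulates ``(site_label, rule)`` pairs attributing
    every dropped site to the single rule that removed it.
    """
    p = p or FilterParams()
    m = _reduce_top_two(m)
    calls = m.calls.copy()

    if m.depths is not None:
        total = m.depths.sum(axis=2)
        bad_depth = (total < p.depth_min) | (total > p.depth_max)
        calls[bad_depth] = MISSING

    present = calls != MISSING
    n_present = present.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_present > 0, het / np.maximum(n_present, 1), 0.0)
        alt_count = np.where(present, calls, 0).sum(axis=0)
        freq = np.where(n_present > 0, alt_count / np.maximum(2 * n_present, 1), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    presence = n_present / max(m.n_individuals, 1)

    drop_het = het_frac > p.max_het_fraction
    drop_maf = ~drop_het & (maf < p.maf_min)
    drop_presence = ~drop_het & ~drop_maf & (presence < p.site_presence_min)
    keep = ~(drop_het | drop_maf | drop_presence)

    if log is not None:
        for j in np.flatnonzero(drop_het):
            log.append((_site_label(m.sites[j]), "het_fraction"))
        for j in np.flatnonzero(drop_maf):
            log.append((_site_label(m.sites[j]), "maf"))
        for j in np.flatnonzero(drop_presence):
            log.append((_site_label(m.sites[j]), "site_presence"))

    if not keep.any():
        logger.warning("filter_sites removed every site")

    out = SnpMatrix(
        individuals=list(m.individuals),
        sites=list(m.sites),
        calls=calls,
        depths=None if m.depths is None else m.depths.copy(),
    )
    return out.take_sites(np.flatnonzero(keep))


def filter_individuals(
    m: SnpMatrix, p: FilterParams | None = None, log: list | None = None
) -> SnpMatrix:
    """Drop individuals whose missing-call fraction exceeds the cap."""
    p = p or FilterParams()
    miss = m.individual_missingness()
    keep = miss <= p.indiv_missing_max
    if log is not None:
        for i in np.flatnonzero(~keep):
            log.append((m.individuals[i].id, "individual_missingness"))
    return m.take_individuals(np.flatnonzero(keep))


def thin_sites(m: SnpMatrix, min_bp: int) -> SnpMatrix:
    """Greedy positional thinning: keep a site iff >= ``min_bp`` from the last
    kept site on the same chromosome (first site per chromosome always kept).
    """
    keep: list[int] = []
    last_chrom: str | None = None
    last_pos = 0
    order = sorted(range(m.n_sites), key=lambda j: (m.sites[j].chrom, m.sites[j].pos))
    for j in order:
        s = m.sites[j]
        if s.chrom != last_chrom or s.pos - last_pos >= min_bp:
            keep.append(j)
            last_chrom, last_pos = s.chrom, s.pos
    return m.take_sites(keep)


def pool_by_site(
    m: SnpMatrix, round_decimals: int = 4
) -> SiteFreqMatrix:
    """Pool genotypes by collection site and estimate per-site allele frequency.

    A collection site is the set of individuals sharing identical coordinates
    after rounding to ``round_decimals`` decimal places.  Individuals without
    coordinates are excluded with a logged warning.
    """
    groups: dict[tuple[float, float], list[int]] = {}
    for i, ind in enumerate(m.individuals):
        if not ind.has_coordinates:
            logger.warning("individual %s has no coordinates; excluded from pooling", ind.id)
            continue
        key = (round(ind.latitude, round_decimals), round(ind.longitude, round_decimals))
        groups.setdefault(key, []).append(i)

    keys = sorted(groups)
    freqs = np.full((len(keys), m.n_sites), np.nan)
    ns = np.zeros(len(keys), dtype=int)
    for s, key in enumerate(keys):
        idx = groups[key]
        sub = m.calls[idx]
        present = sub != MISSING
        n_calls = present.sum(axis=0)
        alt = np.where(present, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[s] = np.where(n_calls > 0, alt / (2.0 * np.maximum(n_calls, 1)), np.nan)
        ns[s] = len(idx)

    return SiteFreqMatrix(
        site_ids=[f"{lat:.{round_decimals}f},{lon:.{round_decimals}f}" for lat, lon in keys],
        latitudes=np.array([k[0] for k in keys]),
        longitudes=np.array([k[1] for k in keys]),
        n=ns,
        freqs=freqs,
    )
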