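"""Sample-size-corrected gene diversity, F-statistics, and Jost's D.

Estimators follow the harmonic-mean sample-size correction of Nei & Chesser
for grouped diploid data.  Per locus, with groups s = 1..S (only groups with
at least one call at the locus included), group sample sizes n_s, alt
frequencies p_s, and observed heterozygosities Ho_s:

    n~  = harmonic mean of n_s
    Ho  = mean_s Ho_s
    Hs  = (n~ / (n~ - 1)) (1 - mean_s sum_a p_sa^2 - Ho / (2 n~))
    Ht  = 1 - sum_a pbar_a^2 + Hs / (n~ S) - Ho / (2 n~ S)

    F_ST = 1 - Hs / Ht        F_IS = 1 - Ho / Hs
    Jost's D = ((Ht - Hs) / (1 - Hs)) * S / (S - 1)

Gene diversity D of a sample of n diploids with alt frequency p is the
sample-size-corrected expected heterozygosity ``(2n / (2n - 1)) (1 - p^2 -
(1-p)^2)``.  Statistics are averaged across loci with per-locus values that
are undefined (monomorphic, empty, or degenerate denominators) excluded per
statistic; negative per-locus values from sampling noise are retained, not
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp import MISSING, SnpMatrix


@dataclass
class GroupedFreqs:
    """Per-group per-locus sample sizes, alt frequencies, observed het."""

    groups: list[str]
    n: np.ndarray   # (S, L) diploid individuals with calls
    p: np.ndarray   # (S, L) alt-allele frequency (NaN where n = 0)
    ho: np.ndarray  # (S, L) observed heterozygosity (NaN where n = 0)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_loci(self) -> int:
        return self.n.shape[1]

    def subset(self, pair: tuple[str, str]) -> "GroupedFreqs":
        idx = [self.groups.index(g) for g in pair]
        return GroupedFreqs(
            groups=list(pair), n=self.n[idx], p=self.p[idx], ho=self.ho[idx]
        )


@dataclass
class DiversityResult:
    """Across-loci means and standard errors of D, F_ST, and F_IS."""

    stats: pd.DataFrame      # index statistic; columns mean, se, n_loci
    per_locus: pd.DataFrame  # per-locus D, F_ST, F_IS (NaN = undefined)
    group_table: pd.DataFrame | None = None  # Table-2-style per-group rows

    def summary(self) -> str:
        out = ["Diversity statistics (mean +/- SE across loci)"]
        for stat, row in self.stats.iterrows():
            out.append(
                f"  {stat:5s}: {row['mean']:.4f} +/- {row['se']:.4f}"
                f"  ({int(row['n_loci'])} loci)"
            )
        if self.group_table is not None:
            out.append(self.group_table.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(out)


def group_freqs(m: SnpMatrix, grouping: dict[str, str] | list | np.ndarray) -> GroupedFreqs:
    """Per-group allele frequencies, sample sizes, and observed heterozygosity.

    ``grouping`` is either a map from individual id to group name or a
    sequence of group labels aligned with the matrix rows (None = excluded).
    """
    if isinstance(grouping, dict):
        unknown = set(grouping) - set(m.ids)
        if unknown:
            raise ValueError(f"grouping refers to unknown individuals: {sorted(unknown)}")
        labels = [grouping.get(ind.id) for ind in m.individuals]
    else:
        labels = list(grouping)
    groups = sorted({g for g in labels if g is not None})
    if not groups:
        raise ValueError("no groups supplied")

    S, L = len(groups), m.n_sites
    n = np.zeros((S, L), dtype=int)
    p = np.full((S, L), np.nan)
    ho = np.full((S, L), np.nan)
    for s, g in enumerate(groups):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        if not idx:
            raise ValueError(f"group {g!r} is empty")
        sub = m.calls[idx]
        present = sub != MISSING
        n[s] = present.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[s] = np.where(
                n[s] > 0,
                np.where(present, sub, 0).sum(axis=0) / (2.0 * np.maximum(n[s], 1)),
                np.nan,
            )
            ho[s] = np.where(
                n[s] > 0, (sub == 1).sum(axis=0) / np.maximum(n[s], 1), np.nan
            )
    return GroupedFreqs(groups=groups, n=n, p=p, ho=ho)


def _nei_arrays(gf: GroupedFreqs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (Ho, Hs, Ht, S_included); NaN where a locus is degenerate.

    Groups with no calls at a locus are dropped from that locus; loci with
    fewer than 2 included groups or harmonic-mean n <= 1 are NaN throughout.
    """
    included = gf.n > 0
    S_l = included.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_n = np.where(included, 1.0 / np.maximum(gf.n, 1), 0.0)
        n_harm = S_l / inv_n.sum(axis=0)
        ho_mean = np.nanmean(np.where(included, gf.ho, np.nan), axis=0)
        sum_p2 = gf.p**2 + (1.0 - gf.p) ** 2
        msp2 = np.nanmean(np.where(included, sum_p2, np.nan), axis=0)
        pbar = np.nanmean(np.where(included, gf.p, np.nan), axis=0)
        sum_pbar2 = pbar**2 + (1.0 - pbar) ** 2

        ok = (S_l >= 2) & (n_harm > 1.0)
        hs = np.where(
            ok,
            (n_harm / (n_harm - 1.0)) * (1.0 - msp2 - ho_mean / (2.0 * n_harm)),
            np.nan,
        )
        ht = np.where(
            ok,
            1.0 - sum_pbar2 + hs / (n_harm * S_l) - ho_mean / (2.0 * n_harm * S_l),
            np.nan,
        )
    ho_out = np.where(ok, ho_mean, np.nan)
    return ho_out, hs, ht, np.where(ok, S_l, np.nan)


def nei_components(gf: GroupedFreqs, locus: int) -> tuple[float, float, float]:
    """Sample-size-corrected (Ho, Hs, Ht) at one locus."""
    ho, hs, ht, _ = _nei_arrays(gf)
    return float(ho[locus]), float(hs[locus]), float(ht[locus])


def gene_diversity(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sample-size-corrected expected heterozygosity (2n/(2n-1))(1 - sum p^2)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 1.0 - p**2 - (1.0 - p) ** 2
        return np.where(n > 0, (2.0 * n / np.maximum(2.0 * n - 1.0, 1e-12)) * raw, np.nan)


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan"), 0
    se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), se, int(v.size)


def f_statistics(gf: GroupedFreqs) -> DiversityResult:
    """Across-loci D, F_ST, F_IS with per-group Table-2-style rows.

    Per-group F_ST is the group's differentiation from the total
    (1 - Hs_group / Ht_all-groups); per-group D and F_IS use that group's
    calls only.
    """
    ho, hs, ht, _ = _nei_arrays(gf)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.abs(ht) > 1e-12, 1.0 - hs / ht, np.nan)
        fis = np.where(np.abs(hs) > 1e-12, 1.0 - ho / hs, np.nan)

    # total-sample gene diversity from pooled calls
    n_tot = gf.n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_tot = np.nansum(np.where(gf.n > 0, gf.n * gf.p, 0.0), axis=0) / np.maximum(
            n_tot, 1
        )
    d_tot = gene_diversity(n_tot, np.where(n_tot > 0, p_tot, np.nan))

    per_locus = pd.DataFrame({"D": d_tot, "F_ST": fst, "F_IS": fis})
    rows = {}
    for stat in ("D", "F_ST", "F_IS"):
        mean, se, k = _mean_se(per_locus[stat].to_numpy())
        rows[stat] = {"mean": mean, "se": se, "n_loci": k}
    stats = pd.DataFrame(rows).T

    # per-group rows
    grows = []
    for s, g in enumerate(gf.groups):
        d_g = gene_diversity(gf.n[s], gf.p[s])
        # group Hs: single-group corrected expected heterozygosity
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = gf.n[s] > 1
            hs_g = np.where(
                ok,
                (gf.n[s] / np.maximum(gf.n[s] - 1.0, 1e-12))
                * (1.0 - gf.p[s] ** 2 - (1.0 - gf.p[s]) ** 2 - gf.ho[s] / (2.0 * np.maximum(gf.n[s], 1))),
                np.nan,
            )
            fst_g = np.where(np.abs(ht) > 1e-12, 1.0 - hs_g / ht, np.nan)
            fis_g = np.where(np.abs(hs_g) > 1e-12, 1.0 - gf.ho[s] / hs_g, np.nan)
        dm, dse, dn = _mean_se(d_g)
        fm, fse, _ = _mean_se(fst_g)
        im, ise, _ = _mean_se(fis_g)
        grows.append(
            {
                "group": g,
                "n_loci": dn,
                "D": dm,
                "D_se": dse,
                "F_ST": fm,
                "F_ST_se": fse,
                "F_IS": im,
                "F_IS_se": ise,
            }
        )
    group_table = pd.DataFrame(grows).set_index("group")
    return DiversityResult(stats=stats, per_locus=per_locus, group_table=group_table)


def jost_d(gf: GroupedFreqs, pair: tuple[str, str] | None = None) -> tuple[float, float]:
    """Mean and SE across loci of Jost's D between exactly two groups."""
    sub = gf if pair is None else gf.subset(pair)
    if sub.n_groups != 2:
        raise ValueError("Jost's D is defined for exactly 2 groups")
    _, hs, ht, S_l = _nei_arrays(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(
            np.abs(1.0 - hs) > 1e-12,
            ((ht - hs) / (1.0 - hs)) * (S_l / (S_l - 1.0)),
            np.nan,
        )
    mean, se, _ = _mean_se(d)
    return mean, se


def jost_d_matrix(gf: GroupedFreqs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric group-pair matrices of mean and SE Jost's D."""
    G = gf.n_groups
    mean = np.zeros((G, G))
    se = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            m, s = jost_d(gf, (gf.groups[i], gf.groups[j]))
            mean[i, j] = mean[j, i] = m
            se[i, j] = se[j, i] = s
    idx = pd.Index(gf.groups)
    return pd.DataFrame(mean, index=idx, columns=idx), pd.DataFrame(se, index=idx, columns=idx)
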