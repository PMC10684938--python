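"""Readers and writers for VCF genotypes, metadata CSV, and SSR tables."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .snp import MISSING, IndividualMeta, SiteMeta, SnpMatrix, SsrTable


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


def read_vcf(path: str | Path, metadata: dict[str, IndividualMeta] | None = None) -> SnpMatrix:
    """Read a diploid VCF into a :class:`SnpMatrix`.

    GT is required; AD (allelic depths) is stored when present.  Multi-allelic
    records are retained with their full allele list and genotype indices so
    that :func:`obake.filters.filter_sites` can perform top-two-allele
    reduction; the dosage matrix initially encodes the count of the first ALT
    allele (calls carrying other ALT alleles are recoded during filtering).

    Parameters
    ----------
    path
        Path to an (optionally bgzipped) VCF 4.x file.
    metadata
        Optional map from sample id to :class:`IndividualMeta`; samples not in
        the map get bare metadata with ``species_label='unknown'``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)

    sites: list[SiteMeta] = []
    site_alleles: list[tuple[str, ...]] = []
    geno_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False

    for rec_i, rec in enumerate(vcf):
        alts = tuple(rec.ALT) if rec.ALT else ()
        alleles = (rec.REF,) + alts
        gt = np.asarray(rec.genotype.array())  # (n, ploidy+1); last col = phasing
        if gt.shape[1] - 1 != 2:
            raise VcfParseError(
                f"record {rec.CHROM}:{rec.POS} (line ~{rec_i + 1}): ploidy "
                f"{gt.shape[1] - 1} != 2"
            )
        pair = gt[:, :2].astype(np.int8)
        pair[pair < 0] = MISSING
        geno_rows.append(pair)

        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0
            # ref depth + total alt depth (top-2 reduction happens later)
            ref_d = ad[:, 0]
            alt_d = ad[:, 1:].sum(axis=1) if ad.shape[1] > 1 else np.zeros(n, dtype=np.int64)
            depth_rows.append(np.stack([ref_d, alt_d], axis=1))
            any_depth = True
        else:
            depth_rows.append(np.zeros((n, 2), dtype=np.int64))

        sites.append(
            SiteMeta(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alts[0] if alts else ".",
            )
        )
        site_alleles.append(alleles)

    genotypes = (
        np.stack(geno_rows, axis=1) if geno_rows else np.zeros((n, 0, 2), dtype=np.int8)
    )
    # dosage of first alt allele; any other alt allele leaves dosage as its count
    # of allele-1 copies (0) until top-2 reduction decides its fate
    calls = np.where(
        (genotypes == MISSING).any(axis=2), MISSING, (genotypes == 1).sum(axis=2)
    ).astype(np.int8)
    depths = np.stack(depth_rows, axis=1) if any_depth else None

    meta = metadata or {}
    individuals = [meta.get(s, IndividualMeta(id=s)) for s in samples]
    return SnpMatrix(
        individuals=individuals,
        sites=sites,
        calls=calls,
        depths=depths,
        genotypes=genotypes,
        site_alleles=site_alleles,
    )


def write_vcf(m: SnpMatrix, path: str | Path) -> None:
    """Write the dosage matrix as an uncompressed biallelic VCF 4.2 file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if m.depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths (ref,alt)">\n'
            )
        for chrom in dict.fromkeys(s.chrom for s in m.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.ids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" if m.depths is None else "GT:AD"
        for j, site in enumerate(m.sites):
            fields = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", "PASS", ".", fmt]
            for i in range(m.n_individuals):
                cell = gt_code[int(m.calls[i, j])]
                if m.depths is not None:
                    cell += f":{int(m.depths[i, j, 0])},{int(m.depths[i, j, 1])}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


def read_metadata_csv(path: str | Path) -> dict[str, IndividualMeta]:
    """Read individual metadata (columns: id, species, accession, lat, lon)."""
    out: dict[str, IndividualMeta] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lat = row.get("lat", "")
            lon = row.get("lon", "")
            out[row["id"]] = IndividualMeta(
                id=row["id"],
                species_label=row.get("species", "unknown") or "unknown",
                accession=row.get("accession", "") or "",
                latitude=float(lat) if lat not in ("", None) else None,
                longitude=float(lon) if lon not in ("", None) else None,
            )
    return out


def write_metadata_csv(individuals: list[IndividualMeta], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "species", "accession", "lat", "lon"])
        for ind in individuals:
            w.writerow(
                [
                    ind.id,
                    ind.species_label,
                    ind.accession,
                    "" if ind.latitude is None else f"{ind.latitude:.6f}",
                    "" if ind.longitude is None else f"{ind.longitude:.6f}",
                ]
            )


def read_ssr_csv(path: str | Path) -> SsrTable:
    """Read a plastid SSR table (columns: id, then one column per locus)."""
    df = pd.read_csv(path, dtype={"id": str})
    loci = [c for c in df.columns if c != "id"]
    alleles = df[loci].fillna(MISSING).to_numpy(dtype=int)
    return SsrTable(individuals=df["id"].tolist(), loci=loci, alleles=alleles)


def write_ssr_csv(t: SsrTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + list(t.loci))
        for i, ind in enumerate(t.individuals):
            w.writerow(
                [ind] + ["" if a == MISSING else int(a) for a in t.alleles[i]]
            )


def write_filter_log(log: list[tuple[str, str]], path: str | Path) -> None:
    """Write the per-site/per-individual removal log as TSV (item, rule)."""
    with open(path, "w") as fh:
        fh.write("item\trule\n")
        for item, rule in log:
            fh.write(f"{item}\t{rule}\n")
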