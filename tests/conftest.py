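"""Shared fixtures and matrix-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from obake.snp import IndividualMeta, SiteMeta, SnpMatrix


def make_matrix(
    calls,
    positions=None,
    chroms=None,
    depths=None,
    species=None,
    coords=None,
) -> SnpMatrix:
    """Build a SnpMatrix from a dosage array with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    positions = positions if positions is not None else [100 * (j + 1) for j in range(L)]
    chroms = chroms if chroms is not None else ["1"] * L
    individuals = []
    for i in range(n):
        lat, lon = (coords[i] if coords is not None else (None, None))
        individuals.append(
            IndividualMeta(
                id=f"ind{i:03d}",
                species_label=species[i] if species is not None else "unknown",
                latitude=lat,
                longitude=lon,
            )
        )
    sites = [SiteMeta(chrom=c, pos=p, ref="A", alt="G") for c, p in zip(chroms, positions)]
    return SnpMatrix(individuals=individuals, sites=sites, calls=calls, depths=depths)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
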