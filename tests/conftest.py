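"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from radpop import forward_sim as fs
from radpop.variant_io import GenotypeMatrix, HaplotypeSet, PopulationMap, VariantTable


def make_variants(n: int, chrom: str = "chr1", spacing: int = 1000) -> VariantTable:
    return VariantTable(
        np.array([chrom] * n, dtype=object),
        (np.arange(n, dtype=np.int64) + 1) * spacing,
        np.array(["A"] * n, dtype=object),
        np.array(["T"] * n, dtype=object),
        np.array([f"{chrom}_m{i}" for i in range(n)], dtype=object),
    )


def make_gm(G: np.ndarray, pops=None, variants: VariantTable | None = None, depths=None):
    """GenotypeMatrix (+ PopulationMap when pops given) from a dosage array."""
    n, L = G.shape
    v = variants if variants is not None else make_variants(L)
    samples = [f"i{i}" for i in range(n)]
    gm = GenotypeMatrix(np.asarray(G, dtype=np.int8), v, samples, depths)
    if pops is None:
        return gm
    pm = PopulationMap(
        {s: p for s, p in zip(samples, pops)}, {s: p for s, p in zip(samples, pops)}
    )
    return gm, pm


@pytest.fixture(scope="session")
def tiny_haps() -> HaplotypeSet:
    """Four haplotypes over four SNPs, hand-checkable for EHHS enumeration."""
    hv = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0]], dtype=np.uint8
    )
    return HaplotypeSet(hv, make_variants(4), ["ind0", "ind1"])


@pytest.fixture(scope="session")
def inversion_cohort() -> fs.Cohort:
    """The default synthetic inversion cohort: two populations of 75, 58
    region SNPs diverged to FST ~0.8, arrangement frequencies 0.95 / 0.05."""
    return fs.simulate_inversion_cohort(
        fs.SimParams(pop_sizes=(75, 75), seed=3),
        fs.InversionParams(),
        missingness=0.05,
    )


@pytest.fixture(scope="session")
def inversion_cohort_complete() -> fs.Cohort:
    """Same structure without missingness (phased haplotypes exported)."""
    return fs.simulate_inversion_cohort(
        fs.SimParams(pop_sizes=(75, 75), seed=3),
        fs.InversionParams(),
        missingness=0.0,
    )


@pytest.fixture(scope="session")
def null_cohort() -> fs.Cohort:
    """Two labelled samples from one panmictic pool: no structure at all."""
    return fs.simulate_null_cohort(n_per_pop=(60, 60), n_snps=400, seed=7)
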