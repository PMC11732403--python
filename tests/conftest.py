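"""Shared fixtures: tiny genotype matrices and cached desk-scale simulations."""

from __future__ import annotations

import numpy as np
import pytest

from perchpop.core import GenotypeMatrix, PopulationMap
from perchpop.sim import (
    constant_ne_scenario,
    make_perch_scenario,
    population_map_for,
    simulate_wright_fisher,
)


def make_gm(
    dosage,
    chrom=None,
    pos=None,
    samples=None,
    contig_lengths=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array (samples x sites)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if pos is None:
        pos = None
        # positions increase within each chromosome
        counts: dict[str, int] = {}
        pos = []
        for c in chrom:
            counts[c] = counts.get(c, 0) + 1
            pos.append(counts[c] * 100)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosage=dosage,
        samples=list(samples),
        contig_lengths=contig_lengths,
    )


@pytest.fixture(scope="session")
def preset_sim():
    """One desk-scale three-population simulation shared across tests."""
    cfg = make_perch_scenario(scale=0.012, seed=0)
    gm, truth = simulate_wright_fisher(cfg)
    return gm, truth, population_map_for(cfg)


@pytest.fixture(scope="session")
def const_sim():
    """One constant-N=100 equilibrium simulation shared across tests."""
    cfg = constant_ne_scenario(seed=0)
    gm, truth = simulate_wright_fisher(cfg)
    return gm, truth, cfg


@pytest.fixture()
def popmap_two():
    return PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
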