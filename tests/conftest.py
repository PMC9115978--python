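"""Shared fixtures: tiny handcrafted datasets and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from rohscan import GenotypeDataset, SampleRecord, SimConfig, VariantRecord, simulate_cohort
from rohscan.genotype_io import MISSING


def make_dataset(calls, positions=None, chroms=None, breeds=None, groups=None):
    """Build a dataset from a calls matrix with sensible defaults."""
    calls = np.asarray(calls, dtype=np.int8)
    n_i, n_s = calls.shape
    if positions is None:
        positions = [100_000 * (j + 1) for j in range(n_s)]
    if chroms is None:
        chroms = [1] * n_s
    if breeds is None:
        breeds = ["B1"] * n_i
    if groups is None:
        groups = ["other"] * n_i  # matches the PLINK readers (group not on disk)
    variants = [
        VariantRecord(f"snp{j}", int(chroms[j]), int(positions[j]), "A", "G")
        for j in range(n_s)
    ]
    samples = [
        SampleRecord(f"s{i}", breed=breeds[i], group=groups[i]) for i in range(n_i)
    ]
    return GenotypeDataset(samples, variants, calls)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort with planted tracts (4 breeds x 10)."""
    config = SimConfig(seed=101, n_breeds=4, individuals_per_breed=10)
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
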