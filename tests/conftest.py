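"""Shared fixtures: a small fast scenario for unit tests and the default
(standard-conditions) scenario, built once per session, for end-to-end
checks."""

from __future__ import annotations

import numpy as np
import pytest

from ggaasat.region_builder import filter_microsatellites, scan_genome
from ggaasat.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def small_config(seed: int = 11) -> SimulationConfig:
    """A miniature scenario (~40x smaller) for unit-level pipeline tests."""
    counts = {1: 60, 2: 30}
    counts.update({c: 8 for c in range(3, 21)})
    return SimulationConfig(
        n_chroms=2,
        chrom_length=400_000,
        regions_per_class=counts,
        n_genes=60,
        n_noise_peaks=10,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def default_sim():
    """The standard study conditions (seed 1) used by the end-to-end
    acceptance checks."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def default_scan(default_sim):
    scan = scan_genome(default_sim.genome, max_gap=default_sim.config.max_gap)
    msats = filter_microsatellites(scan.final)
    return scan, msats
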