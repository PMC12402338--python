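"""Shared fixtures: small simulated experiments reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from pairedtag import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimConfig:
    """Compact default experiment: full planted design at reduced cell count."""
    return sim.default_config(seed=42, n_cells_per_group=60,
                              fragments_per_cell_dna=600)


@pytest.fixture(scope="session")
def small_truth(small_config) -> sim.SimTruth:
    return sim.simulate_cells(small_config)


@pytest.fixture(scope="session")
def small_genome(small_config):
    cfg = small_config.replace(chromosome_length=120_000, n_chromosomes=2,
                               n_genes=12, cell_types=(), type_marked_genes={},
                               planted_bivalency={}, expression_effect={})
    return sim.generate_toy_genome(cfg), cfg


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
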