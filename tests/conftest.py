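from __future__ import annotations

import numpy as np
import pytest

from eqtlpath import (
    PlantedSignal,
    ScenarioConfig,
    simulate_scenario,
)


@pytest.fixture(scope="session")
def small_cfg() -> ScenarioConfig:
    """A down-scaled scenario for fast unit tests."""
    return ScenarioConfig(
        seed=11,
        n_chroms=2,
        chrom_length_bp=2_000_000,
        n_genes=80,
        n_pathways=10,
        pathway_size=8,
        n_tissues=2,
        eqtls_per_gene=2,
        n_query_variants=8,
        flank_bp=50_000,
    )


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    return simulate_scenario(small_cfg)


@pytest.fixture(scope="session")
def planted_cfg() -> ScenarioConfig:
    """Reference conditions with the planted tissue-pathway signal."""
    return ScenarioConfig(
        seed=3, planted=PlantedSignal("tissue1", "PW001", 8.0)
    )


@pytest.fixture(scope="session")
def planted_scenario(planted_cfg):
    return simulate_scenario(planted_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
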