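import numpy as np
import pytest

from pprealu.synthetic_data import (
    SimulationConfig,
    builtin_alu_library,
    generate_genome_with_annotations,
)


@pytest.fixture(scope="session")
def alu_library():
    return builtin_alu_library()


@pytest.fixture(scope="session")
def clean_synthetic(alu_library):
    """Seed-1 genome: 50 genes, 10 planted configurations, no Alu divergence."""
    cfg = SimulationConfig(seed=1, n_genes=50, n_planted_configs=10, alu_mutation_rate=0.0)
    return cfg, generate_genome_with_annotations(cfg, alu_library)


@pytest.fixture(scope="session")
def diverged_synthetic(alu_library):
    """Seed-2 genome with Alu copies mutated at 10% (motif region protected)."""
    cfg = SimulationConfig(seed=2, n_genes=50, n_planted_configs=10, alu_mutation_rate=0.10)
    return cfg, generate_genome_with_annotations(cfg, alu_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
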