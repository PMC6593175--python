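import pytest

from zgapipe import SimulationConfig, run_pipeline
from zgapipe.synthetic_data import simulate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact embryo for fast unit tests (dense genome, 300 genes)."""
    return SimulationConfig(seed=11, n_genes=300, intergenic_gap_mean_bp=8000.0)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study: 2,000 genes, seed 7."""
    return simulate_bundle(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_report(default_bundle):
    return run_pipeline(bundle=default_bundle)
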