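import random

import pytest

from polyorigin import synthetic_data as sd


@pytest.fixture(scope="session")
def allo_dataset():
    """Small deep-divergence ALLO dataset shared across tests."""
    cfg = sd.ScenarioConfig(
        n_loci=3,
        n_diploid_species=4,
        tetraploid_samples=2,
        polyploidy_time=2e6,
        error_rate=0.0,
        seed=42,
    )
    return sd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def allo_truths():
    """Truth gene trees from a deep ALLO scenario (no sequences/reads)."""
    cfg = sd.ScenarioConfig(
        n_loci=20,
        n_diploid_species=5,
        hybrid_parents=("D1", "D3"),
        polyploidy_time=2e6,
        tetraploid_samples=2,
        seed=7,
    )
    net = sd.build_scenario(cfg)
    return cfg, sd.simulate_gene_trees(net, cfg, rng=random.Random(7))
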