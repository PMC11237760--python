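import numpy as np
import pytest

from crisprcensus.simulate import ArraySpec, SimConfig, generate_host_genome

FOUR_TYPE_SPECS = [
    ArraySpec("C", 37, 10, 0.02, 34, 0.65),
    ArraySpec("B", 36, 10, 0.02, 35, 0.65),
    ArraySpec("G", 36, 10, 0.02, 36, 0.65),
    ArraySpec("E", 29, 10, 0.02, 31, 0.65),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_genome():
    """One 60-kb contig with three clean C-type arrays and its truth."""
    cfg = SimConfig(seed=11, n_arrays=3)
    rec, truth = generate_host_genome(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def mixed_genome():
    """One 120-kb contig with ten arrays covering all four repeat types."""
    cfg = SimConfig(seed=42, n_arrays=10, array_specs=FOUR_TYPE_SPECS,
                    genome_length=120_000)
    rec, truth = generate_host_genome(cfg)
    return cfg, rec, truth
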