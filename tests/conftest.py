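import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from herivome.simulate import SimulationConfig

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def small_config():
    """A fast, single-segment configuration for unit tests."""
    return SimulationConfig(seed=11, n_segments=1, genome_length=1000,
                            reads_per_contig=1000,
                            eve_duplication=(600, 800),
                            conserved_motifs=[(100, 31), (300, 35), (450, 39)])


@pytest.fixture
def rng():
    return np.random.default_rng(99)
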