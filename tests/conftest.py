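import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genes():
    from chromtargets.genome_io import GeneModel

    return [
        GeneModel("gA", "chr1", 5000, 8000, "+"),
        GeneModel("gB", "chr1", 12000, 14000, "-"),
        GeneModel("gC", "chr2", 1000, 2000, "+"),
    ]
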