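import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from dcx.contrast import ContrastModel
from dcx.synthetic import SyntheticMSAConfig, generate_helix, generate_msa


@pytest.fixture(scope="session")
def benchmark_msa():
    """The standard planted benchmark: 50 fore / 200 back, L=100, 10 pattern
    columns at theta 0.9 vs background 0.05, seed 1."""
    return generate_msa(SyntheticMSAConfig(), seed=1)


@pytest.fixture(scope="session")
def benchmark_results(benchmark_msa):
    aln, part, _ = benchmark_msa
    return ContrastModel(aln, part).fit()


@pytest.fixture(scope="session")
def helix12():
    return generate_helix(12)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
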