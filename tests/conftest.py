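import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluxscreen import build_manifest, make_pseudogenes

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def screen_manifest():
    """Full-size manifest under the screening composition (489 genes)."""
    return build_manifest(seed=11)


@pytest.fixture(scope="session")
def screen_pseudogenes(screen_manifest):
    return make_pseudogenes(screen_manifest, len(screen_manifest.genes), seed=12)


@pytest.fixture(scope="session")
def small_manifest():
    """A 5-gene manifest with 60 NTCs for fast unit tests."""
    return build_manifest({"SLC": 5}, two_tss_genes=1, n_ntc=60, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
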