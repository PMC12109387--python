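import numpy as np
import pytest

from toothseg.io_formats import normalize_cloud
from toothseg.synthetic import ArchSpec, generate_arch


@pytest.fixture(scope="session")
def small_cloud():
    """One normalized full-dentition cloud, 2048 points."""
    cloud = generate_arch(ArchSpec(points_per_cloud=2048, seed=42))
    return normalize_cloud(cloud)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
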