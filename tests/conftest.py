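import numpy as np
import pytest

from phylounits.core import Site
from phylounits.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic survey under the default study conditions."""
    return generate_dataset(SimulationConfig(seed=20230420))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, quick dataset for I/O and pipeline smoke tests."""
    cfg = SimulationConfig(n_sites=40, n_watersheds=3, n_clades=3,
                           majority_prob=(0.8, 0.8, 0.8), seed=7)
    return generate_dataset(cfg)


@pytest.fixture
def toy_sites():
    """Six collinear sites, two spatially compact clades split at lon 2.5."""
    return [Site(site_id=f"s{i}", lat=0.0, lon=float(i),
                 watershed_id="A" if i < 3 else "B",
                 clade="CA" if i < 3 else "CB")
            for i in range(6)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
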