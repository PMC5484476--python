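import numpy as np
import pytest

from igspec import (
    PopulationConfig,
    generate_dataset,
    lab_instrument,
)
from igspec.synthetic import default_components


@pytest.fixture(scope="session")
def small_dataset():
    """60 samples x 2 replicates on the lab profile; shared, treat as read-only."""
    return generate_dataset(PopulationConfig(n_samples=60), instrument=lab_instrument(), seed=11)


@pytest.fixture(scope="session")
def noiseless_rank3_dataset():
    """Three independent spectral components, all noise off: exact Beer-Lambert data."""
    comps = tuple(c for c in default_components() if c.name != "matrix")
    inst = lab_instrument(
        noise_sd=0.0, baseline_offset_sd=0.0, baseline_slope_sd=0.0, scatter_sd=0.0, replicates=1
    )
    pop = PopulationConfig(n_samples=90, reference_cv=0.0)
    return generate_dataset(pop, components=comps, instrument=inst, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
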