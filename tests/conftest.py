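import numpy as np
import pytest

from archetyper.synthetic_data import SyntheticSpec, plant_family, \
    plant_support_tree


@pytest.fixture(scope="session")
def small_family():
    """A 4-subfamily, 3-proteins-each synthetic family with truth."""
    spec = SyntheticSpec(n_per_subfamily=3, seed=11)
    proteins, hits, truth = plant_family(spec)
    return spec, proteins, hits, truth


@pytest.fixture(scope="session")
def small_tree():
    spec = SyntheticSpec(n_per_subfamily=3, seed=11)
    return spec, *plant_support_tree(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
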