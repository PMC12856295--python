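import numpy as np
import pytest

from rofbes import RoFHyperparams, SyntheticConfig, fit_rof, generate_synthetic


@pytest.fixture(scope="session")
def small_data():
    """Separable synthetic table: 120 x 8 with 3 planted features."""
    data, informative = generate_synthetic(
        SyntheticConfig(n=120, p=8, n_informative=3, effect_size=2.0, seed=11)
    )
    return data, informative


@pytest.fixture(scope="session")
def small_model(small_data):
    data, _ = small_data
    hp = RoFHyperparams(n_estimators=15, min_group=2, max_group=4,
                        remove_proportion=0.25)
    return fit_rof(data, hp, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
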