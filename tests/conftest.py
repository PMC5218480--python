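import numpy as np
import pandas as pd
import pytest

from synergykit import MedianEffectFit, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def fast_config():
    """Small, quiet simulation config for unit tests."""
    return SimulationConfig(seed=11, n_genes=400, samples_per_condition=3,
                            n_animals_per_group=6, n_replicates=2)


def exact_fit(m: float, dm: float) -> MedianEffectFit:
    """A median-effect fit object with known true parameters."""
    return MedianEffectFit(m=m, dm=dm, r=1.0, n_points=0)


def median_effect_fa(doses, m, dm):
    doses = np.asarray(doses, dtype=float)
    return 1.0 / (1.0 + (dm / doses) ** m)


@pytest.fixture
def exact_fit_factory():
    return exact_fit
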