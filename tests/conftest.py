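import numpy as np
import pytest

from polypdemog import GrowthParams, SimulationConfig


@pytest.fixture(scope="session")
def general_params():
    """General growth curve pooled across all six sites."""
    return GrowthParams(l_inf=15.4, k=0.062)


@pytest.fixture(scope="session")
def calafuria_params():
    """Growth curve of the coldest site."""
    return GrowthParams(l_inf=8.6, k=0.185)


@pytest.fixture(scope="session")
def site_sst():
    """Mean annual SST (°C) of the six sites, north to south."""
    return np.array([19.556, 18.023, 18.737, 19.138, 19.537, 19.875])


@pytest.fixture()
def default_config():
    return SimulationConfig(seed=11)


def single_site_config(z, n_target, max_age=30, seed=0, **kw):
    """One-site configuration for targeted generator checks."""
    defaults = dict(
        site_labels=("S1",), sst_means=(19.0,), l_inf=(15.4,), k=(0.062,),
        z=(z,), n_patches=(3,), n_target=(n_target,), max_age=max_age, seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
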