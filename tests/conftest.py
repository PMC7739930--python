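import numpy as np
import pandas as pd
import pytest

from conservebias import experiments, synthio


@pytest.fixture(scope="session")
def demo_data() -> synthio.SyntheticData:
    """A mid-sized synthetic dataset with multi-species projects."""
    return synthio.generate_dataset(synthio.SynthConfig(n_species=200, seed=42))


@pytest.fixture(scope="session")
def model_table() -> pd.DataFrame:
    """Analysis table whose counts follow the NB mixed model exactly."""
    cfg = synthio.SynthConfig(n_species=300, seed=7, multi_species_fraction=0.0)
    return experiments.make_model_table(synthio.generate_dataset(cfg))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
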