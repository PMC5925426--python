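import numpy as np
import pytest

import infantpk as ip
from infantpk.dataset import CleaningRules


@pytest.fixture(scope="session")
def final_model():
    return ip.build_final_model()


@pytest.fixture(scope="session")
def study_dataset(final_model):
    """One synthetic study at the published final-model parameters."""
    return ip.generate_study(final_model, seed=20201)


@pytest.fixture(scope="session")
def clean_dataset(study_dataset):
    ds, _ = ip.apply_cleaning(study_dataset, CleaningRules())
    return ds


@pytest.fixture(scope="session")
def final_fit(final_model, clean_dataset):
    """FOCE-I fit of the final model structure on the session study."""
    return ip.fit(final_model, clean_dataset, ip.FitOptions(compute_se=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
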