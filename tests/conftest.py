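import numpy as np
import pytest

from sysmetab.chemometrics import OPLSDA
from sysmetab.nmr import bucket_samples
from sysmetab.synthetic import SyntheticConfig, generate_spectra


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def spectra_and_truth(default_config):
    return generate_spectra(default_config)


@pytest.fixture(scope="session")
def bucket_matrix(spectra_and_truth):
    spectra, _ = spectra_and_truth
    return bucket_samples(spectra)


@pytest.fixture(scope="session")
def fitted_oplsda(bucket_matrix):
    model = OPLSDA.from_bucket_matrix(bucket_matrix, "model", "control", n_orth=1)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
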