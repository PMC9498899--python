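import numpy as np
import pytest

from ccchkit.synthetic_data import PlantSpec, generate_dataset, study_family


@pytest.fixture(scope="session")
def study():
    """The 46-protein study-profile family plus its truth table."""
    return study_family(seed=11)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Default 200-protein synthetic dataset for recall/precision checks."""
    return generate_dataset(PlantSpec(n_proteins=200, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
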