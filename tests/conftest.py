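import hypothesis
import pytest

from apamirna import ApaMirnaShiftModel
from apamirna.simulate import SyntheticConfig, fixture_small, generate_dataset

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def small_ds():
    """Hand-written 12-gene / 4-family dataset with known values."""
    return fixture_small()


@pytest.fixture(scope="session")
def small_results(small_ds):
    model = ApaMirnaShiftModel.from_synthetic(dataset=small_ds)
    return model.fit(seed=5, n_resamples=30)


@pytest.fixture(scope="session")
def medium_null_ds():
    """Moderate null-model dataset shared by statistical unit tests."""
    return generate_dataset(SyntheticConfig(n_genes=800, n_families=20,
                                            seed=42))
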