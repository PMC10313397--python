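import pytest
from hypothesis import settings

from shapetaste import ChainConfig, fit_taste, make_study_dataset

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_table():
    """One study-like dataset (n=24, clipped) shared across tests."""
    return make_study_dataset(seed=7)


@pytest.fixture(scope="session")
def quick_chains():
    """Reduced chain configuration for tests that need a real fit but not
    the full study-scale draw count."""
    return ChainConfig(
        n_chains=4, n_iterations=1500, burn_in=500, seed=11, proposals_per_draw=10
    )


@pytest.fixture(scope="session")
def sweetness_fit(study_table, quick_chains):
    """A converged sweetness fit on the shared dataset."""
    return fit_taste(study_table, "sweetness", chains=quick_chains)
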