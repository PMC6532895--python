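import pytest

import econclusters as ec


@pytest.fixture(scope="session")
def small_sim():
    """A small, well-separated synthetic survey shared across tests."""
    spec = ec.default_spec(n_households=800, corruption=0.02, n_noise_assets=2, seed=11)
    return ec.simulate_survey(spec)


@pytest.fixture(scope="session")
def small_model(small_sim):
    config = ec.SearchConfig(
        n_assets=5, k_range=(4, 6), mode="threshold", asw_threshold=0.70,
        min_prevalence=0.10,
    )
    return ec.search(small_sim.households, config)
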