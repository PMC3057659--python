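import numpy as np
import pytest

from pulsedepth import synthetic as syn


@pytest.fixture(scope="session")
def default_params():
    return syn.GeneratorParams()


@pytest.fixture(scope="session")
def clean_params():
    """Generator with every waveform disturbance switched off."""
    return syn.GeneratorParams().noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 40-subject labelled cohort (20 floating / 20 sunken)."""
    return syn.simulate_cohort(20, 20, seed=7)
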