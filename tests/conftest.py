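import numpy as np
import pytest

from tmapro import GeneratorConfig, simulate_study
from tmapro.io import write_study


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 0), shared across the suite."""
    return simulate_study(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    """Same cohort with urine measurement noise disabled (exact relations)."""
    return simulate_study(GeneratorConfig(seed=0, urine_noise_sd=0.0))


@pytest.fixture(scope="session")
def fixture_dir(default_study, tmp_path_factory):
    """The default study written out as a fixture directory."""
    outdir = tmp_path_factory.mktemp("fixture")
    write_study(default_study, outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
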