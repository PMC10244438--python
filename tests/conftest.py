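import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import seconsensus as sc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params():
    """A fast three-dataset study used by unit (non-acceptance) tests."""
    return sc.SimulationParams(
        seed=7,
        n_chroms=1,
        chrom_length=4_000_000,
        n_genes=40,
        n_datasets=3,
        n_shared_gain_se=1,
        n_private_gain_se=1,
        n_lost_se=1,
        n_constitutive_se=2,
        n_background_peaks=30,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    return sc.simulate_study(small_params)


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    sc.write_study(small_study, out)
    return out


def constant_track(value=2.0, length=100_000, bin_width=50, chrom="chr1"):
    n = -(-length // bin_width)
    return sc.SignalTrack(
        bins={chrom: np.full(n, float(value))}, bin_width=bin_width
    )


@pytest.fixture
def flat_track():
    return constant_track()
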