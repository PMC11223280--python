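import numpy as np
import pytest

from eegfc.signal_prep import BANDS
from eegfc.synth import SyntheticStudySpec, gen_study


@pytest.fixture(scope="session")
def theta():
    return BANDS["theta"]


@pytest.fixture(scope="session")
def alpha():
    return BANDS["alpha"]


@pytest.fixture(scope="session")
def small_study():
    """Six-subject (2/group) theta+alpha study, scaled down (fs 250, 19 s)."""
    spec = SyntheticStudySpec(
        n_subjects_per_group=(2, 2, 2),
        fs=250.0,
        duration_s=19.0,
        bands=("theta", "alpha"),
        seed=42,
    )
    return gen_study(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
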