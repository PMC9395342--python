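import numpy as np
import pytest

from brainprint import CohortSpec, EpochsTensor, make_cohort


def make_tensor(c=4, t=10, n=6, sfreq=200.0, seed=0, **meta):
    """Random Gaussian epochs block for unit tests."""
    rng = np.random.default_rng(seed)
    meta.setdefault("individual_id", "sub-00")
    meta.setdefault("session_id", "ses-00")
    return EpochsTensor(
        data=rng.standard_normal((c, t, n)),
        sfreq=sfreq,
        channel_names=[f"ch{i}" for i in range(c)],
        **meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_tensor():
    return make_tensor()


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-session strong-signal cohort shared across tests."""
    spec = CohortSpec(K=4, S=2, C=16, T=100, N=60, seed=42)
    return make_cohort(spec)


@pytest.fixture(scope="session")
def small_pair(small_cohort):
    return small_cohort.pair("ses-00", "ses-01")
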