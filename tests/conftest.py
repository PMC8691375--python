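"""Shared fixtures: phantom bank features are extracted once per session."""
import numpy as np
import pytest

from aaamorph.synthetic_cohort import bank_features, default_phantom_bank


@pytest.fixture(scope="session")
def phantom_bank():
    return default_phantom_bank()


@pytest.fixture(scope="session")
def phantom_bank_feats(phantom_bank):
    """Features of the default bank (memoized; drives cohort simulation)."""
    return bank_features(phantom_bank)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
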