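import dataclasses
import warnings

import numpy as np
import pytest

from scrkit.synth import SyntheticConfig, simulate_cohort, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_participants=4, seed=7)


@pytest.fixture(scope="session")
def session(small_config):
    return simulate_session(small_config, "P01")


@pytest.fixture(scope="session")
def small_cohort(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_sheet(small_config):
    """Feature sheet + SAM responses for a 4-participant synthetic cohort."""
    from scrkit.pipeline import RunConfig, compute_feature_sheet

    cfg = RunConfig(seed=7)
    cfg.synthetic = dataclasses.replace(small_config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sheet, sam = compute_feature_sheet(cfg)
    return sheet, sam
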