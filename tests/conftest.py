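import numpy as np
import pytest

from westgardqc.datasets import load_study_config, reference_summaries
from westgardqc.simulate import default_config, generate_study


@pytest.fixture(scope="session")
def study_config():
    return load_study_config()


@pytest.fixture(scope="session")
def reference():
    """Published per-phase CV/bias/sigma matrix of the monitored study."""
    return reference_summaries()


@pytest.fixture(scope="session")
def synthetic_study():
    """One default in-control synthetic study (5 analytes, 2 levels, 88 runs)."""
    cfg = default_config(seed=20240608)
    results, peer, truth = generate_study(cfg)
    return cfg, results, peer, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
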