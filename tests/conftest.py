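import numpy as np
import pytest

import tcommit as tc
from tcommit.experiments import wt_report

BASE_SEED = 1


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture
def grn_params():
    return tc.GRNParameters()


@pytest.fixture
def epi_params():
    return tc.EpigeneticParameters()


@pytest.fixture
def config():
    return tc.default_config()


@pytest.fixture(scope="session")
def wt_ensemble():
    """30 wild-type colonies shared by the ensemble-level statistics tests."""
    cfg = tc.default_config()
    report, cats, trees = wt_report(30, cfg, seed=BASE_SEED, return_trees=True)
    return trees, report, cats
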