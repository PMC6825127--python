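import numpy as np
import pandas as pd
import pytest

from germline_nog import MSSConfig, SyntheticConfig, generate_cohort, run_pipeline

#: Small cohort used by cross-module tests; sized for seconds, not power.
DESK_CONFIG = dict(
    n_genes=300, n_train=100, n_test=50, n_valid=100,
    n_hallmarks=4, hallmark_size=80, rng_seed=11,
)
DESK_MSS = dict(n_rounds=500, min_hits=60, rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SyntheticConfig(**DESK_CONFIG))


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    return run_pipeline(small_cohort, mss_config=MSSConfig(**DESK_MSS))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
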