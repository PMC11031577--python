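import warnings

import numpy as np
import pytest

from radrobust.preprocessing import preprocess_cohort
from radrobust.robustness import concordance_table
from radrobust.simulate import PRESETS, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-center cohort with designed robustness structure."""
    ds, gt = simulate_cohort(PRESETS["tiny"](1))
    return ds, gt


@pytest.fixture(scope="session")
def tiny_records(tiny_cohort):
    ds, _ = tiny_cohort
    return concordance_table(ds)


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    ds, _ = tiny_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed, state = preprocess_cohort(ds)
    return processed, state


@pytest.fixture(scope="session")
def screen_cohort():
    """Mid-size cohort for predictive-direction checks (fast but informative)."""
    cfg = PRESETS["paper_like_small"](5)
    cfg.n_center_a = 220
    cfg.n_center_b = 60
    ds, gt = simulate_cohort(cfg)
    rec = concordance_table(ds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed, _ = preprocess_cohort(ds)
    return processed, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
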