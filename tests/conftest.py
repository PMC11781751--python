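import numpy as np
import pytest

from lbwdetect.preprocess import Preprocessor
from lbwdetect.synth import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(
        n_samples=400,
        prevalence=(0.15, 0.05, 0.02),
        severity=2.0,
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cfg, small_cohort):
    df, truth = small_cohort
    fm = Preprocessor(small_cfg.schema()).fit(df).transform(df)
    return fm, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
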