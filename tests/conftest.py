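import numpy as np
import pandas as pd
import pytest

from fcserology import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One 13-vs-10 cohort with the default effect profile."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """A cohort with every group effect switched off."""
    cfg = CohortConfig(seed=7)
    cfg.effect_sizes = {k: 0.0 for k in cfg.effect_sizes}
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
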