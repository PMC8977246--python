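import numpy as np
import pytest

from survipw import Design1, Design2, SurvivalDataset, gen_design1, gen_design2


@pytest.fixture(scope="session")
def toy():
    """Eight subjects, two strata, two covariates, two missing cells."""
    z1 = np.array([0.5, -1.0, 2.0, 0.0, 1.5, -0.5, 1.0, 0.2])
    z2 = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    mask = np.ones((8, 2), dtype=bool)
    mask[2, 0] = False
    mask[5, 0] = False
    Z = np.where(mask, np.column_stack([z1, z2]), np.nan)
    return SurvivalDataset(
        time=np.array([2.0, 1.0, 3.0, 2.5, 1.5, 0.8, 2.2, 1.2]),
        event=np.array([1, 1, 0, 1, 1, 1, 1, 0]),
        stratum=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        Z=Z, mask=mask, covariate_names=["z1", "z2"],
        stratum_labels=["a", "b"],
    )


@pytest.fixture(scope="session")
def d1_small():
    return gen_design1(Design1(n=400, event_rate=0.7), seed=12345)


@pytest.fixture(scope="session")
def d1_mid():
    return gen_design1(Design1(n=2000, event_rate=0.7), seed=9876)


@pytest.fixture(scope="session")
def d2_small():
    return gen_design2(Design2(n=800), seed=2468)
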