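import numpy as np
import pytest

from lqrg import (
    LQParams,
    LQRGParams,
    TumorSpec,
    group_representative_schedule,
)

#: (mean total dose Gy, median fraction size Gy, mean GTV volume cm^3) per group
GROUP_SUMMARIES = {
    "A": (62.92, 2.1, 105.83),
    "B": (64.07, 2.4, 102.21),
    "C": (62.89, 2.8, 108.51),
}


@pytest.fixture(scope="session")
def lqrg_params():
    return LQRGParams()


@pytest.fixture(scope="session")
def lq_params():
    return LQParams()


@pytest.fixture(scope="session")
def group_schedules():
    return {
        name: group_representative_schedule(dose, frac)
        for name, (dose, frac, _vol) in GROUP_SUMMARIES.items()
    }


@pytest.fixture(scope="session")
def group_tumors():
    return {name: TumorSpec(vol) for name, (_d, _f, vol) in GROUP_SUMMARIES.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
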