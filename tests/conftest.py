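import pytest

from ablink import NoiseParams, TrainingScenario, load_preset
from ablink.presets import (
    NOVICES,
    PRACTITIONERS_T1,
    PRACTITIONERS_T2,
)


@pytest.fixture(scope="session")
def time1():
    """Pre-training reference model (calibrated gains, reference noise)."""
    return load_preset("time1")


@pytest.fixture(scope="session")
def time2():
    """Post-training reference model."""
    return load_preset("time2")


@pytest.fixture(scope="session")
def practitioners():
    return TrainingScenario(
        group="practitioners",
        time1_noise=NoiseParams(*PRACTITIONERS_T1),
        time2_noise=NoiseParams(*PRACTITIONERS_T2),
    )


@pytest.fixture(scope="session")
def novices():
    return TrainingScenario(
        group="novices",
        time1_noise=NoiseParams(*NOVICES),
        time2_noise=NoiseParams(*NOVICES),
    )
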