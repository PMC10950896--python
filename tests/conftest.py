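import numpy as np
import pytest

from potency_uq import (
    SyntheticClassConfig,
    SyntheticPredictionConfig,
    generate_activity_class,
    generate_prediction_set,
)

#: small, fast class for model unit tests
SMALL_CONFIG = SyntheticClassConfig(n_compounds=300, n_bits=256, n_signal_bits=48, seed=1)


@pytest.fixture(scope="session")
def small_class():
    return generate_activity_class(SMALL_CONFIG, class_id="small")


@pytest.fixture(scope="session")
def default_class_2000():
    return generate_activity_class(SyntheticClassConfig(seed=0), class_id="default")


@pytest.fixture(scope="session")
def calibrated_set():
    """Perfectly calibrated by construction (c = 1), n = 1e5."""
    return generate_prediction_set(
        SyntheticPredictionConfig(n=100_000, sigma_law=0.8, calibration_factor=1.0, seed=3)
    )
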