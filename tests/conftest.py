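import dataclasses

import numpy as np
import pytest

from limbkin.calibration import build_correction_model, fit_calibration
from limbkin.synthetic import (
    PlatformModel,
    bradypus_defaults,
    generate_calibration_dataset,
)


@pytest.fixture(scope="session")
def platform():
    """Default distorting platform (compliance, cross-talk, sensor noise)."""
    return PlatformModel()


@pytest.fixture(scope="session")
def noiseless_platform():
    return PlatformModel(noise_sd_n=0.0)


@pytest.fixture(scope="session")
def identity_platform():
    """A platform that records the applied force exactly."""
    return PlatformModel(
        diag_center=(1.0, 1.0, 1.0),
        diag_edge_drop=(0.0, 0.0, 0.0),
        zx_bend_gain=0.0,
        zy_gain_center=0.0,
        zy_gain_edge=0.0,
        xz_gain=0.0,
        yz_gain_edge=0.0,
        offsets_center_n=(0.0, 0.0, 0.0),
        oz_edge_n=0.0,
        noise_sd_n=0.0,
    )


@pytest.fixture(scope="session")
def exact_model(noiseless_platform):
    """Correction model fitted on noiseless calibration data."""
    obs = generate_calibration_dataset(noiseless_platform)
    return build_correction_model(fit_calibration(obs))


@pytest.fixture(scope="session")
def noisy_model(platform):
    """Correction model fitted under the default sensor noise."""
    obs = generate_calibration_dataset(platform, seed=97)
    return build_correction_model(fit_calibration(obs))


@pytest.fixture(scope="session")
def small_hind_cohort_spec():
    return dataclasses.replace(bradypus_defaults("hindlimb"), n_contacts=25)


@pytest.fixture(scope="session")
def small_fore_cohort_spec():
    return dataclasses.replace(bradypus_defaults("forelimb"), n_contacts=25)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
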