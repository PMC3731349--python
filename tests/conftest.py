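import numpy as np
import pytest

from ceusperf import (
    AcquisitionSpec,
    GammaVariateParams,
    NoiseModel,
    simulate_tic,
)


@pytest.fixture
def truth_params() -> GammaVariateParams:
    """Reference bolus kinetics used throughout: modest wash-in over a
    small baseline, arrival 5 s into a 160 s acquisition."""
    return GammaVariateParams(A=2.0, alpha=0.25, t0=5.0, C=0.5)


@pytest.fixture
def acq_10hz() -> AcquisitionSpec:
    return AcquisitionSpec(duration=160.0, frame_rate=10.0)


@pytest.fixture
def clean_tic(truth_params, acq_10hz):
    return simulate_tic(truth_params, acq_10hz, NoiseModel())


@pytest.fixture
def param_rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_params(rng: np.random.Generator) -> GammaVariateParams:
    """A random valid parameter draw over a broad physiological range."""
    return GammaVariateParams(
        A=float(rng.uniform(0.1, 50.0)),
        alpha=float(rng.uniform(0.02, 2.0)),
        t0=float(rng.uniform(0.0, 20.0)),
        C=float(rng.uniform(-5.0, 20.0)),
    )
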