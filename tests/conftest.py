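import numpy as np
import pytest

from amoebatrack import TwoPhaseParams

# parameter ranges bracketing the published behavioral fits
PARAM_RANGES = {
    "cIA": (30.0, 400.0),
    "cCA": (0.0, 2000.0),
    "tx": (1.0, 8.0),
    "tp": (3.0, 15.0),
    "tc": (20.0, 120.0),
    "tg": (1.0, 10.0),
}


def draw_params(rng: np.random.Generator) -> TwoPhaseParams:
    return TwoPhaseParams(**{k: rng.uniform(*v) for k, v in PARAM_RANGES.items()})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hour_grid():
    """0-200 h at 0.5 h steps, the standard recording resolution."""
    return np.arange(0.0, 200.1, 0.5)
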