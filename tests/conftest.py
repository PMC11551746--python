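import numpy as np
import pytest

from strandex.reactions import (
    DEFAULT_THREE_STEP_RATES,
    DEFAULT_TWO_STEP_RATES,
    RateConstants,
    ReactionState,
)


@pytest.fixture
def three_step_rates() -> RateConstants:
    return DEFAULT_THREE_STEP_RATES


@pytest.fixture
def two_step_rates() -> RateConstants:
    return DEFAULT_TWO_STEP_RATES


@pytest.fixture
def standard_state() -> ReactionState:
    """Standard assay condition: 36 nM filament + 36 nM donor duplex."""
    return ReactionState(A=36.0, B=36.0)


@pytest.fixture
def coarse_grid() -> np.ndarray:
    return np.arange(0.0, 1001.0, 20.0)


def random_rate_constants(rng: np.random.Generator) -> RateConstants:
    """Log-uniform positive rates spanning realistic kinetic ranges."""
    lo = np.log10([1e-5, 1e-4, 1e-4, 1e-4, 1e-4, 1e-6])
    hi = np.log10([1e-2, 1e-1, 1e-1, 1e-1, 1e-1, 1e-3])
    return RateConstants(*(10.0 ** rng.uniform(lo, hi)))
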