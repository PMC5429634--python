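"""Shared fixtures: synthetic records reused across test modules.

The quail-like record is expensive to generate (full-length pilot
calibration), so it is session-scoped.
"""

import numpy as np
import pytest

from ultrarhythm.io_timeseries import LocomotionSeries, bin_to_actogram
from ultrarhythm.synthetic_data import (
    RhythmComponent,
    SyntheticSpec,
    gen_fractal_locomotion,
)


@pytest.fixture(scope="session")
def quail_series() -> LocomotionSeries:
    """Default quail-like synthetic record (6.5 d, 0.5 s, full rhythm set)."""
    return gen_fractal_locomotion(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def rhythmic_series() -> LocomotionSeries:
    """Record with a strong 24 h + 12 h rhythm mixture, for detection tests."""
    spec = SyntheticSpec(
        seed=0,
        components=[RhythmComponent(24.0), RhythmComponent(12.0)],
        rhythm_strength=0.8,
    )
    return gen_fractal_locomotion(spec)


@pytest.fixture(scope="session")
def quail_actogram_30s(quail_series):
    return bin_to_actogram(quail_series, 30.0)


@pytest.fixture(scope="session")
def rhythmic_actogram_6min(rhythmic_series):
    return bin_to_actogram(rhythmic_series, 360.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
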