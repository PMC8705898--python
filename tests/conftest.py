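import numpy as np
import pytest
from hypothesis import settings

from topeq.kinetics import CellConfig, CumulativeProfile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def ivrt_cell() -> CellConfig:
    return CellConfig(receptor_volume_ml=12.0, sample_volume_ml=0.3, diffusion_area_cm2=1.54)


@pytest.fixture
def unit_cell() -> CellConfig:
    """1 cm² cell for hand-computable mass balances."""
    return CellConfig(receptor_volume_ml=12.0, sample_volume_ml=0.3, diffusion_area_cm2=1.0)


def make_profile(times, q, replicate_id="r1", q_unit="ug/cm2") -> CumulativeProfile:
    return CumulativeProfile(
        replicate_id=replicate_id, times_h=tuple(times), q=tuple(q), q_unit=q_unit
    )


@pytest.fixture
def higuchi_profile():
    """Exact square-root-of-time profile with K = 10 over the 6 h schedule."""
    t = np.array([0.5, 1, 2, 3, 4, 5, 6], dtype=float)
    return make_profile(t, 10.0 * np.sqrt(t))
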