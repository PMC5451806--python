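import numpy as np
import pytest

from cordsim import default_params, make_profile, simulate
from cordsim.geometry import build_cord_grid

HOUR = 3600.0


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def pk1():
    return make_profile("pk1")


@pytest.fixture(scope="session")
def pk3():
    return make_profile("pk3")


@pytest.fixture(scope="session")
def cord_run_pk1(params, pk1):
    """Baseline full-cord 72 h run under the single short infusion."""
    return simulate.run("cord", params, pk1, 72 * HOUR)


@pytest.fixture(scope="session")
def cord_run_pk3(params, pk3):
    """Baseline full-cord 72 h run under the 3 h constant profile."""
    return simulate.run("cord", params, pk3, 72 * HOUR)


@pytest.fixture(scope="session")
def clamped_long_run(params, pk1):
    """Clamped-vessel radial (single-disc) run to 1000 h with cross terms."""
    p = params.replace(m_discs=1)
    return simulate.run(
        "clamped", p, pk1, 1000 * HOUR, grid=build_cord_grid(p), track_cross=True
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
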