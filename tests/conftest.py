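"""Shared fixtures.

Expensive Monte-Carlo artifacts (averaged profiles, surfing curves) are
session-scoped so independent tests reuse one computation.  All randomness
is seeded; the suite is deterministic.
"""

import numpy as np
import pytest

from genesurf import ModelParams, average_profile, solve_surfing_bvp
from genesurf.surfing import relax_wave, surfing_curve


@pytest.fixture(scope="session")
def fast_params():
    return ModelParams(N=50, a=0.2, b=0.3, L=120)


@pytest.fixture(scope="session")
def relaxed_fast(fast_params):
    return relax_wave(fast_params, burn_in=120.0, seed=101)


@pytest.fixture(scope="session")
def profile_n300():
    """Averaged wildtype wave profile at N=300, a=0.2 (theory-grade)."""
    p = ModelParams(N=300, a=0.2, b=0.3, L=160)
    return average_profile(p, burn_in=120.0, n_snapshots=400,
                           snapshot_interval=1.0, seed=211,
                           speed_duration=4000.0)


@pytest.fixture(scope="session")
def theory_n300(profile_n300):
    return solve_surfing_bvp(profile_n300, b=0.3)


@pytest.fixture(scope="session")
def mc_curve_n300():
    """Monte-Carlo surfing curve at N=300, a=0.2, b=0.3 (s = 0.5)."""
    p = ModelParams(N=300, a=0.2, b=0.3, L=120)
    grid = np.arange(-15.0, 27.1, 3.0)
    curve = surfing_curve(p, grid, n_reps=500, seed=307, burn_in=120.0)
    return p, curve


@pytest.fixture(scope="session")
def profile_fast(fast_params):
    """Averaged profile for the fast preset (N=50, a=0.2)."""
    return average_profile(fast_params, burn_in=100.0, n_snapshots=300,
                           snapshot_interval=1.0, seed=401,
                           speed_duration=2000.0)
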