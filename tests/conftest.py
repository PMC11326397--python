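"""Shared fixtures: simulated datasets and fitted models reused across tests.

The expensive genome-scale fits are session-scoped so that parameter
recovery, calibration, credible-set coverage and power-consistency checks
all share the same five seeded runs.
"""

import numpy as np
import pytest

from gwfm import SimConfig
from gwfm.pipeline import simulate_and_fit
from gwfm.sampler import McmcConfig

N_SPARSE_SEEDS = 5


@pytest.fixture(scope="session")
def sparse_fits():
    """Five seeded sparse-architecture simulations fitted with the point-normal model."""
    fits = []
    for seed in range(N_SPARSE_SEEDS):
        cfg = SimConfig(seed=seed)  # m=5000, n=10000, h2=0.5, 1% causal
        fits.append(
            simulate_and_fit(
                cfg, "sbayesc", McmcConfig(n_iter=10_000, burn_in=2_000, seed=seed + 100)
            )
        )
    return fits


@pytest.fixture(scope="session")
def small_fit():
    """One small sparse simulation with genotypes kept, for cheap end-to-end checks."""
    cfg = SimConfig(m=500, n=4_000, block_size=50, seed=1)
    return simulate_and_fit(
        cfg,
        "sbayesc",
        McmcConfig(n_iter=3_000, burn_in=1_000, seed=11),
        keep_genotypes=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
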