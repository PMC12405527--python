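import numpy as np
import pytest

from mutburst import colony, sweep

# Fixed suite-wide seed for the expensive shared simulations.
SUITE_SEED = 20240901

#: Wild-type reporter rates: segmental duplication (D) and canavanine
#: resistance (C), per cell per division.
WT_RATES = colony.RateSet(colony.RATE_D, colony.RATE_C, labels=("D", "C"))


@pytest.fixture(scope="session")
def null_batch_100k():
    """100,000 null-model colonies at the wild-type D/C rates, G = 27."""
    return colony.simulate_null_batch(WT_RATES, 27, 100_000, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def null_model_rates(null_batch_100k):
    return colony.estimate_model_rates(null_batch_100k)


@pytest.fixture(scope="session")
def paper_sweep():
    """Default mutator-parameter sweep against the wild-type observations."""
    grid = sweep.SweepGrid()
    observed = sweep.ObservedRates.wild_type_dc()
    return sweep.run_sweep(grid, observed, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def paper_sweep_fine():
    """Same sweep at 48x the realizations per point: the accepted set's
    regime statistics (simultaneous shares, onset generations) rest on a
    handful of double-mutant events per point at the 1000-realization
    floor, so the finer run is what the regime assertions read."""
    grid = sweep.SweepGrid(n_realizations=48_000)
    observed = sweep.ObservedRates.wild_type_dc()
    return sweep.run_sweep(grid, observed, seed=SUITE_SEED)
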