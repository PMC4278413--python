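import numpy as np
import pytest

import cbf3select as cs
from cbf3select.clock_driver import REGIMES, simulate_clock


@pytest.fixture(scope="session")
def regime_ld():
    return REGIMES["12L/12D"]


@pytest.fixture(scope="session")
def regime_ll():
    return REGIMES["24L/0D"]


@pytest.fixture(scope="session")
def wt_clock_ld():
    return simulate_clock(REGIMES["12L/12D"], duration=96.0, step=0.5)


@pytest.fixture(scope="session")
def clocks_all():
    """Wild-type clock trajectories for all four regimes (fitting grid)."""
    return {label: simulate_clock(REGIMES[label], duration=96.0, step=0.25) for label in REGIMES}


def sample_trajectory(traj, times):
    """Model values at measurement times, transient cycle discarded."""
    return np.interp(24.0 + np.asarray(times, float), traj.times, traj.mrna)


@pytest.fixture(scope="session")
def noiseless_from_model(clocks_all):
    """Factory: noiseless multi-regime dataset generated by a known model."""

    def make(arch, params, times=None):
        times = np.arange(0.0, 48.0 + 1e-9, 4.0) if times is None else np.asarray(times)
        datasets = {}
        for label, clock in clocks_all.items():
            traj = cs.simulate_cbf3(clock, arch, params)
            datasets[label] = cs.ExpressionDataset(
                times=times,
                values=sample_trajectory(traj, times),
                regime=REGIMES[label],
                noise_sd=0.0,
                seed=0,
            )
        return datasets

    return make
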