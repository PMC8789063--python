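import numpy as np
import pytest

import junctionmd as jm


@pytest.fixture(scope="session")
def j1_topology():
    return jm.load_builtin_topology("J1")


@pytest.fixture(scope="session")
def j24_topology():
    return jm.load_builtin_topology("J24")


@pytest.fixture(scope="session")
def small_step_ensemble():
    """Tiny synthetic duplex ensemble with rebuilt coordinates (5 frames)."""
    spec = jm.StepEnsembleSpec(n_frames=5)
    series, ens = jm.gen_step_ensemble(spec, seed=11, rebuild_coordinates=True)
    return spec, series, ens


@pytest.fixture(scope="session")
def planted_mode_data():
    """Two planted collective modes (9, 1 A^2) under per-frame rigid motions."""
    spec = jm.ModeEnsembleSpec(n_atoms=40, n_frames=4000,
                               mode_variances=(9.0, 1.0), noise_sigma2=0.01)
    frames, mean, modes, prov = jm.gen_mode_ensemble(spec, seed=21)
    return spec, frames, mean, modes


def ar1_series(rng, phi, n, sigma=1.0):
    """Fast scalar AR(1) draw with innovation variance sigma^2."""
    from scipy.signal import lfilter

    eps = rng.normal(0.0, sigma, n)
    return lfilter([1.0], [1.0, -phi], eps)
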