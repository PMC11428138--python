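import numpy as np
import pytest

from specmap import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def dw_traj():
    """Double-well Langevin trajectory (h=5, moderate length)."""
    cfg = synthetic.LangevinConfig(
        potential=synthetic.double_well(5.0),
        beta=1.0,
        dt=1e-3,
        n_steps=10_000_000,
        seed=11,
        thin=1,
    )
    return synthetic.simulate_langevin(cfg)


@pytest.fixture(scope="session")
def lifted_double_well():
    """Lifted double-well benchmark with known slow coordinate.

    Deep wells (h=8) subsampled to 2000 frames; the slow signal, the
    mixing matrix and the feature matrix are all returned.
    """
    cfg = synthetic.LangevinConfig(
        potential=synthetic.double_well(8.0),
        beta=1.0,
        dt=1e-3,
        n_steps=4_000_000,
        seed=2,
        thin=400,
    )
    z_full = synthetic.simulate_langevin(cfg)
    rng = np.random.default_rng(7)
    sel = np.sort(rng.choice(z_full.size, 2000, replace=False))
    z = z_full[sel]
    X, truth = synthetic.lift(
        z, synthetic.LiftConfig(n_features=10, n_fast=3, seed=5), dt=0.4
    )
    return {"X": X, "z": z, "truth": truth}
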