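import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trajvib as tv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def water_traj():
    """Thermal 3-atom harmonic fixture (canonical amplitudes), short run."""
    spec = tv.water_like_spec(n_frames=2**13, seed=11)
    return tv.harmonic_trajectory(spec), spec


@pytest.fixture
def small_traj():
    """Tiny 2-atom trajectory with velocities for plumbing tests."""
    rng = np.random.default_rng(3)
    atoms = tv.AtomTable(["O", "H"], np.array([15.999, 1.008]), ["a", "b"])
    pos = rng.normal(size=(12, 2, 3))
    vel = rng.normal(size=(12, 2, 3))
    return tv.Trajectory(atoms, pos, vel, 0.5)
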