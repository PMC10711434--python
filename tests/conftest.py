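import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

from dnapull import toysim  # noqa: E402


@pytest.fixture(scope="session")
def bdna():
    """Idealized high-affinity-sequence duplex on a cylinder."""
    return toysim.ideal_bdna("GCAATATATTGC")


@pytest.fixture(scope="session")
def bdna_traj(bdna):
    return toysim.make_trajectory(bdna, n_frames=3)


@pytest.fixture(scope="session")
def dbd_fragment():
    return toysim.synthetic_dbd_fragment()


@pytest.fixture(scope="session")
def gaussian_ensemble():
    """10^4 Gaussian work curves, mu=10, sd=1 kcal/mol (seeded)."""
    return toysim.gaussian_work_ensemble(10.0, 1.0, 10_000, seed=11)


@pytest.fixture(scope="session")
def flat_drag_runs():
    """Flat-potential dragged-trap ensemble, 200 runs (seeded)."""
    spec = toysim.LangevinSpec(potential="flat", dt=0.004, n_steps=2000, seed=42)
    sched = toysim.ToySchedule(k_trap=5.0, x0=1.0, x1=-1.0, n_runs=200)
    return toysim.simulate_steered_langevin(spec, sched)


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a random (seeded) rotation + translation to (N, 3) coords."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(0, 2.0, size=3)
    return coords @ rot.T + shift
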