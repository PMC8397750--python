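import numpy as np
import pytest

from ringdrift import synthetic
from ringdrift.benchmarks import circular_correlation  # noqa: F401 (shared)


@pytest.fixture(scope="session")
def small_params() -> synthetic.SyntheticParams:
    """A small but structurally complete synthetic configuration."""
    return synthetic.SyntheticParams(
        n_neurons=30, n_weeks=4, trials_per_week=8, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """(dff, spikes, ground truth) for the small configuration."""
    return synthetic.generate_dataset(small_params)


@pytest.fixture(scope="session")
def planted_ring():
    """Noisy circle embedded in 50-D by a random isometry, with angles.

    Returns (points, true_angle); the embedding should recover the circular
    coordinate.
    """
    rng = np.random.default_rng(42)
    n = 1200
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    circle = np.c_[np.cos(theta), np.sin(theta)]
    circle += 0.02 * rng.normal(size=circle.shape)
    basis, _ = np.linalg.qr(rng.normal(size=(50, 2)))
    points = circle @ basis.T
    return points, theta
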