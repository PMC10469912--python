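import numpy as np
import pytest

from earmorph import (
    SimulationConfig,
    base_ear_shape,
    default_template,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def base_shape(template):
    return base_ear_shape(template)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic training cohort."""
    return simulate_cohort(SimulationConfig(size_scale=0.06, seed=11))


def random_similarity(rng, config):
    """Apply a random rotation, positive scale and translation."""
    angle = rng.uniform(-np.pi, np.pi)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    scale = float(np.exp(rng.uniform(-1.0, 1.0)))
    shift = rng.uniform(-50.0, 50.0, size=2)
    return scale * config @ rot.T + shift


def noisy_ears(rng, base, n, noise=2.0):
    """n perturbed copies of the base ear under random similarity transforms."""
    return np.stack(
        [
            random_similarity(rng, base + rng.normal(0.0, noise, size=base.shape))
            for _ in range(n)
        ]
    )
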