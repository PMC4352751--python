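"""Shared fixtures: every dataset is generated programmatically."""

import numpy as np
import pytest
from hypothesis import settings

from fireflysvm import Dataset, SynthSpec, generate

settings.register_profile("default", derandomize=True)
settings.load_profile("default")


@pytest.fixture
def two_point_toy() -> Dataset:
    """The analytically solvable pair: x = 0 and 1 in 1-D, labels +1/-1.

    With gamma = ln 2 the kernel cross-term is exactly 1/2, so the dual
    reduces to the one-variable problem 2a - a^2 (1 - 1/2).
    """
    return Dataset(np.array([[0.0], [1.0]]), np.array([1, -1]))


@pytest.fixture
def blobs20() -> Dataset:
    """Small well-separated binary blobs (n=20, d=2)."""
    return generate(SynthSpec(kind="gaussian_blobs", n_per_class=10,
                              separation=6.0, seed=42))


@pytest.fixture
def blobs_overlap() -> Dataset:
    """Overlapping binary blobs (n=24): a problem with training errors."""
    return generate(SynthSpec(kind="gaussian_blobs", n_per_class=12,
                              separation=1.5, seed=7))


def random_feasible_alpha(rng: np.random.Generator, y: np.ndarray, C: float) -> np.ndarray:
    """A random multiplier vector repaired onto the constraint set."""
    from fireflysvm import project_feasible

    return project_feasible(rng.uniform(0.0, C, size=y.size), C, y)
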