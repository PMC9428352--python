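import numpy as np
import pytest
from hypothesis import settings

from smrsim.task import default_stack

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stack():
    """Default spherical-model stack (lead field built once per session)."""
    return default_stack()


@pytest.fixture(scope="session")
def montage(stack):
    return stack.montage


@pytest.fixture(scope="session")
def leadfield(stack):
    return stack.leadfield


def fib_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
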