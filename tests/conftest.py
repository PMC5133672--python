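import numpy as np
import pytest

from defcyto import (
    RenderSpec,
    ViscoelasticCellSpec,
    simulate_event,
)


@pytest.fixture
def noise_free_render() -> RenderSpec:
    return RenderSpec(noise_sd=0.0)


@pytest.fixture
def basic_cell() -> ViscoelasticCellSpec:
    return ViscoelasticCellSpec(initial_diameter=15.0, max_strain=0.5,
                                creep_time=2.0, rng_seed=11)


@pytest.fixture
def noise_free_event(basic_cell, noise_free_render):
    return simulate_event(basic_cell, noise_free_render)


def circle_contour(radius: float, center=(0.0, 0.0), n: int = 256) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n + 1)
    return np.column_stack([center[0] + radius * np.sin(t),
                            center[1] + radius * np.cos(t)])


def ellipse_contour(a: float, b: float, angle: float = 0.0,
                    center=(0.0, 0.0), n: int = 512) -> np.ndarray:
    """Closed (row, col) contour of an ellipse with semi-axes a (col) and b."""
    t = np.linspace(0, 2 * np.pi, n + 1)
    x, y = a * np.cos(t), b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack([center[0] + (x * s + y * c),
                            center[1] + (x * c - y * s)])
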