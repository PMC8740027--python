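import numpy as np
import pytest

from divmap import (
    PatternConfig,
    pentaray_patch_layout,
    sample_multisite,
    simulate_activation_field,
)
from divmap.rbf import MultisiteRecording, fit_interpolant


@pytest.fixture(scope="session")
def patch_layout():
    return pentaray_patch_layout()


@pytest.fixture(scope="session")
def focal_field():
    """Homogeneous focal pattern at the reference speed, ideal times."""
    return simulate_activation_field(
        PatternConfig(pattern="focal_homogeneous", time_quantum=0.0)
    )


@pytest.fixture(scope="session")
def plane_field():
    return simulate_activation_field(PatternConfig(pattern="plane", time_quantum=0.0))


@pytest.fixture(scope="session")
def linear_recording(patch_layout):
    """Times exactly affine in position: t = 1 + 2x + 3y."""
    pts = patch_layout.points
    t = 1.0 + 2.0 * pts[:, 0] + 3.0 * pts[:, 1]
    return MultisiteRecording(pts, t, 150.0, patch_layout.labels)


def random_recording(seed, n_sites=15, span=12.0):
    """A random scattered recording with a smooth underlying time field."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-span, span, size=(n_sites, 2))
    src = rng.uniform(-5, 5, size=2)
    c = rng.uniform(0.3, 0.9)
    t = np.hypot(*(pts - src).T) / c + rng.normal(0, 1.0, n_sites)
    return MultisiteRecording(pts, t, 150.0)


@pytest.fixture(scope="session")
def random_models():
    """A pool of fitted models on random recordings for oracle checks."""
    return [fit_interpolant(random_recording(s)) for s in range(12)]
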