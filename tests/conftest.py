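import numpy as np
import pytest

from fundusnorm.phantom import PhantomSpec, generate_phantom, generate_cohort


def circle_mask(shape, center, radius):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(shape, center, b, a):
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    return ((rr - center[0]) / b) ** 2 + ((cc - center[1]) / a) ** 2 <= 1.0


@pytest.fixture(scope="session")
def phantom_30deg():
    """Reference 30-degree disc-centered phantom (disc ratio 0.23)."""
    return generate_phantom(
        PhantomSpec(512, 512, disc_ratio=0.23, vcdr=0.3, seed=1)
    )


@pytest.fixture(scope="session")
def phantom_45deg():
    """45-degree macula-style phantom (disc ratio 0.15)."""
    return generate_phantom(
        PhantomSpec(512, 512, fov_degrees=45.0, disc_ratio=0.15, vcdr=0.4, seed=2)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """20 participants, 25% prevalence, 256-px phantoms."""
    template = PhantomSpec(256, 256, disc_ratio=0.23, vessel_count=4)
    return generate_cohort(20, 0.25, template, seed=7)
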