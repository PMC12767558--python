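import numpy as np
import pytest

from periquant import phantom

#: Scaled-down geometry for fast unit tests; the default study geometry
#: (7 x 1 mm implant, 5 mm defect) is exercised where the physical numbers
#: matter.
SMALL_GEOMETRY = dict(
    implant_width_mm=2.0,
    implant_thickness_mm=0.5,
    defect_width_mm=1.4,
    canvas_margin_mm=0.5,
)


@pytest.fixture
def small_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(noise_sd=0.0, seed=11, **SMALL_GEOMETRY)


@pytest.fixture
def small_phantom(small_spec):
    return phantom.generate_histology_phantom(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask_pair(rng, shape=(64, 64), p_implant=0.05, p_bone=0.3):
    """A random implant/bone mask pair with a guaranteed nonempty implant."""
    implant = rng.random(shape) < p_implant
    implant[shape[0] // 2, shape[1] // 2] = True
    bone = (rng.random(shape) < p_bone) & ~implant
    return implant, bone
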