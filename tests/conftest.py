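import numpy as np
import pytest

from thermoface.phantom import PhantomSpec, SuiteRanges, generate_phantom, generate_suite

# Sub-pixel head-center offset used by single-phantom tests: a cut line
# falling exactly on a pixel-row boundary (as happens with all-integer
# geometry) makes one-row inclusion a measure-zero coin flip; generic
# positions avoid that degeneracy.
GENERIC_CENTER = (70.4, 60.3)


@pytest.fixture(scope="session")
def suite200():
    """The 200-frame seeded phantom suite under the study conditions."""
    suite, manifest = generate_suite(200, SuiteRanges(), master_seed=1)
    return suite, manifest


@pytest.fixture()
def eye_phantom():
    """A rotated no-glasses phantom with known geometry."""
    spec = PhantomSpec(seed=5, head_center=GENERIC_CENTER, beta_deg=10.0)
    frame, truth = generate_phantom(spec)
    return spec, frame, truth


@pytest.fixture()
def glasses_phantom():
    """A glasses phantom with known lens centers."""
    spec = PhantomSpec(seed=11, head_center=GENERIC_CENTER, has_glasses=True)
    frame, truth = generate_phantom(spec)
    return spec, frame, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
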