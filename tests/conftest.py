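import numpy as np
import pytest

from dapcal import make_field
from dapcal.types import DoseMap2D, FieldSpec


@pytest.fixture(scope="session")
def cone_spec() -> FieldSpec:
    """5 cm diameter cone field, 3 mm penumbra, 4% out-of-field plateau."""
    return FieldSpec("cone", 5.0, penumbra_sigma=3.0, tail_frac=0.04, tail_decay=0.0)


@pytest.fixture(scope="session")
def cone_map(cone_spec) -> DoseMap2D:
    """Relative dose map of the cone field, 12 cm extent at 0.5 mm pitch."""
    return make_field(cone_spec, extent=12.0, pitch=0.5)


@pytest.fixture(scope="session")
def square_1x1_spec() -> FieldSpec:
    """1 x 1 cm^2 MLC field with the measured ~4% out-of-field plateau."""
    return FieldSpec("square", 1.0, penumbra_sigma=2.0, tail_frac=0.04, tail_decay=0.0)


@pytest.fixture(scope="session")
def gaussian_map() -> DoseMap2D:
    """Purely analytic Gaussian field, sigma = 1 cm, for closed-form checks."""
    n = 241
    origin = ((n - 1) / 2.0, (n - 1) / 2.0)
    idx = np.arange(n, dtype=float)
    x = (idx - origin[1]) * 0.5 / 10.0
    rr2 = x[None, :] ** 2 + x[:, None] ** 2
    return DoseMap2D(np.exp(-rr2 / 2.0), 0.5, origin)
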