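import numpy as np
import pytest

from tikscape import FieldSpec, build_difference_operator, build_smoother, generate_field


@pytest.fixture
def tundra_spec() -> FieldSpec:
    """The reference tundra parameterization: 62x62 grid of 4 m pixels,
    target mean 0.54 and variance 0.009."""
    return FieldSpec(n_rows=62, n_cols=62, pixel_size=4.0,
                     mu_target=0.54, sigma2_target=0.009, gamma=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def small_field(rng):
    """A quick 24x24 field with moderate smoothing, for downstream stages."""
    spec = FieldSpec(n_rows=24, n_cols=24, pixel_size=4.0, gamma=5.0)
    smoother = build_smoother(build_difference_operator(24, 24), 5.0)
    grid, _ = generate_field(spec, smoother=smoother, rng=rng)
    return grid
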