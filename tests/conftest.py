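import numpy as np
import pytest

import loopdose as ld

H0_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
D_GRID = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
DEFAULT_T = 10.0

# untreated steady state of the default parameters, frozen from an
# independent bisection (brentq) on -0.1*x**3 + x**2 - 1.1*x + 1 = 0
X_STAR_DEFAULT = 8.889084119894873


@pytest.fixture(scope="session")
def default_params():
    return ld.ModelParams()


@pytest.fixture(scope="session")
def rect_surface(default_params):
    """Full default sweep, rectangular wave (additive coupling, T=10)."""
    return ld.sweep_grid(default_params, "rectangular", H0_GRID, D_GRID, T=DEFAULT_T)


@pytest.fixture(scope="session")
def halfsine_surface(default_params):
    """Full default sweep, half-sine wave (additive coupling, T=10)."""
    return ld.sweep_grid(default_params, "halfsine", H0_GRID, D_GRID, T=DEFAULT_T)


@pytest.fixture(scope="session")
def mult_params():
    """Proportional-kill variant of the model (sensitivity configuration)."""
    return ld.ModelParams(coupling="multiplicative")


@pytest.fixture(scope="session")
def mult_rect_surface(mult_params):
    """Full sweep under proportional kill at fast forcing (T=1)."""
    return ld.sweep_grid(mult_params, "rectangular", H0_GRID, D_GRID, T=1.0)


@pytest.fixture(scope="session")
def mult_halfsine_surface(mult_params):
    return ld.sweep_grid(mult_params, "halfsine", H0_GRID, D_GRID, T=1.0)
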