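import numpy as np
import pytest

from bombpulse import AtmosphericCurve, synthetic_bomb_curve


@pytest.fixture(scope="session")
def bomb_curve() -> AtmosphericCurve:
    """Synthetic southern-hemisphere-shaped pulse at 0.05-yr tabulation."""
    return synthetic_bomb_curve(0.05)


@pytest.fixture(scope="session")
def bomb_curve_exact(bomb_curve) -> AtmosphericCurve:
    """Same pulse with zero curve uncertainty, for noise-free identity checks."""
    return AtmosphericCurve(year=bomb_curve.year, f14c=bomb_curve.f14c,
                            sigma=np.zeros(len(bomb_curve)))


@pytest.fixture(scope="session")
def affine_curve() -> AtmosphericCurve:
    """F_atm(u) = 1 + 0.01 (u - 1950) on [1940, 2000], zero curve sigma."""
    year = np.arange(1940.0, 2001.0)
    return AtmosphericCurve(year=year, f14c=1.0 + 0.01 * (year - 1950.0),
                            sigma=np.zeros_like(year))


@pytest.fixture(scope="session")
def flat_curve() -> AtmosphericCurve:
    """Constant curve F = 1 (equilibrium fixed point for any turnover rate)."""
    year = np.arange(1900.0, 2021.0, 5.0)
    return AtmosphericCurve(year=year, f14c=np.ones_like(year),
                            sigma=np.zeros_like(year))
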