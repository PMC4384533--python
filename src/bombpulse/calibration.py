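"""Inversion of fraction-modern values against an atmospheric curve.

A bomb-pulse calibration maps a measured F14C value back onto calendar
years.  Because the pulse rises (1955-1965) and then falls, any value
between the present-day level and the 1965 peak intersects the curve twice,
so the posterior over calendar years is generally bimodal; the posterior is
reported in full, carved into modes, with highest-posterior-density (HPD)
intervals and a configurable single point estimate.

Likelihood
----------
For a measurement F +/- s and curve value mu(t) with curve uncertainty
sc(t), the density at calendar year t is Gaussian:

    L(t) = N(F; mu(t), s^2 + sc(t)^2)

The posterior is L(t) times a uniform prior over a user-set year range,
normalised on a regular grid.  Modes are maximal contiguous runs of grid
cells with posterior above (peak x 1e-3).  HPD intervals collect grid cells
in descending density until the requested mass (68.3% / 95.4%) is reached.

Point-estimate rules
--------------------
``highest-mass``
    posterior mean within the mode carrying the most mass (ties broken
    toward the earlier mode) — the default.
``nearest``
    posterior mean of the mode whose mean lies nearest a supplied reference
    year; useful in validation studies where an independent documented date
    exists.

:func:`invert_monotone` is the deterministic counterpart: on a limb where
the curve is strictly monotone it finds the unique year whose interpolated
curve value equals a target, by bisection.  It serves as an independent
oracle for :func:`calibrate` in the small-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ams import F14CValue
from .atmosphere import AtmosphericCurve
from .errors import (CalibrationError, DegenerateLikelihoodError, DomainError,
                     ParameterError)

__all__ = [
    "Mode",
    "CalibrationResult",
    "likelihood_over_years",
    "calibrate",
    "invert_monotone",
]

#: Posterior cells below peak * this threshold terminate a mode.
MODE_THRESHOLD = 1e-3
HPD_LEVELS = (0.683, 0.954)


@dataclass(frozen=True)
class Mode:
    """A contiguous calendar-year solution region of the posterior."""

    year_lo: float
    year_hi: float
    mass: float
    mean: float


@dataclass(frozen=True)
class CalibrationResult:
    """Posterior over calendar years for one calibrated measurement."""

    year_grid: np.ndarray
    posterior: np.ndarray
    modes: tuple[Mode, ...]
    hpd_68: tuple[tuple[float, float], ...]
    hpd_95: tuple[tuple[float, float], ...]
    point_estimate: float
    point_rule: str
    selected_mode: int
    flags: tuple[str, ...] = ()

    @property
    def predicted_sigma(self) -> float:
        """Half-width of the 68.3% HPD of the selected mode, in years."""
        return mode_hpd_halfwidth(self)

    def summary(self) -> str:
        lines = [f"point estimate: {self.point_estimate:.2f}  "
                 f"(rule: {self.point_rule}, +/- {self.predicted_sigma:.2f} yr)"]
        for i, m in enumerate(self.modes):
            tag = " *" if i == self.selected_mode else ""
            lines.append(f"mode {i}: [{m.year_lo:.2f}, {m.year_hi:.2f}] "
                         f"mass={m.mass:.4f} mean={m.mean:.2f}{tag}")
        for name, ints in (("hpd68", self.hpd_68), ("hpd95", self.hpd_95)):
            for lo, hi in ints:
                lines.append(f"{name}: [{lo:.2f}, {hi:.2f}]")
        return "\n".join(lines)


def likelihood_over_years(meas: F14CValue, curve: AtmosphericCurve,
                          year_grid: np.ndarray) -> np.ndarray:
    """Gaussian calibration likelihood of ``meas`` at each grid year.

    The variance is the measurement variance plus the interpolated curve
    variance.  Grid years must lie inside the curve domain.
    """
    year_grid = np.asarray(year_grid, dtype=float)
    mu = curve.values(year_grid)
    var = meas.sigma ** 2 + curve.sigmas(year_grid) ** 2
    dens = np.zeros_like(mu)
    zero = var == 0.0
    if np.any(zero):
        exact = zero & (mu == meas.f14c)
        if np.any(exact):
            dens[exact] = np.inf
        if np.all(zero) and not np.any(exact):
            raise DegenerateLikelihoodError(
                "zero combined variance everywhere and no exact curve match"
            )
    ok = ~zero
    dens[ok] = np.exp(-0.5 * (meas.f14c - mu[ok]) ** 2 / var[ok]) \
        / np.sqrt(2.0 * np.pi * var[ok])
    return dens


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs (stop inclusive)."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    yield from zip(starts, stops)


def _hpd_intervals(grid: np.ndarray, posterior: np.ndarray, level: float):
    """Smallest grid-cell set holding ``level`` of the mass, as year intervals."""
    order = np.argsort(posterior, kind="stable")[::-1]
    csum = np.cumsum(posterior[order])
    k = int(np.searchsorted(csum, level * csum[-1]))
    chosen = np.zeros(len(posterior), dtype=bool)
    chosen[order[:k + 1]] = True
    return tuple((float(grid[a]), float(grid[b])) for a, b in _runs(chosen))


def mode_hpd_halfwidth(result: CalibrationResult, level: float = 0.683) -> float:
    """Half-width of the ``level`` HPD of the selected mode (>= half a grid step)."""
    grid, post = result.year_grid, result.posterior
    m = result.modes[result.selected_mode]
    sl = (grid >= m.year_lo) & (grid <= m.year_hi)
    ints = _hpd_intervals(grid[sl], post[sl], level)
    lo = min(i[0] for i in ints)
    hi = max(i[1] for i in ints)
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.0
    return max((hi - lo) / 2.0, step / 2.0)


def calibrate(meas: F14CValue, curve: AtmosphericCurve,
              prior_range: tuple[float, float] | None = None,
              grid_step: float = 0.05,
              point_rule: str = "highest-mass",
              reference_year: float | None = None,
              mode_threshold: float = MODE_THRESHOLD) -> CalibrationResult:
    """Calibrate a fraction-modern value to a posterior over calendar years.

    Parameters
    ----------
    meas : F14CValue
        Measured fraction modern with one-sigma uncertainty.
    curve : AtmosphericCurve
        Atmospheric reference record.
    prior_range : (year_lo, year_hi), optional
        Uniform prior support; defaults to the full curve domain.  Must lie
        inside the curve domain (no extrapolation).
    grid_step : float
        Posterior grid resolution in years.
    point_rule : {"highest-mass", "nearest"}
        Rule collapsing a (possibly multimodal) posterior to one year.
    reference_year : float, optional
        Required by the ``nearest`` rule.
    """
    if grid_step <= 0 or not np.isfinite(grid_step):
        raise ParameterError(f"grid_step must be > 0, got {grid_step!r}")
    lo_c, hi_c = curve.domain
    if prior_range is None:
        prior_range = (lo_c, hi_c)
    lo, hi = float(prior_range[0]), float(prior_range[1])
    if lo >= hi:
        raise ParameterError(f"empty prior range ({lo}, {hi})")
    if lo < lo_c or hi > hi_c:
        raise DomainError(
            f"prior range [{lo}, {hi}] outside curve domain [{lo_c}, {hi_c}]"
        )
    n = int(np.floor((hi - lo) / grid_step + 1e-9))
    grid = lo + grid_step * np.arange(n + 1)

    flags: tuple[str, ...] = ()
    mu = curve.values(grid)
    var = meas.sigma ** 2 + curve.sigmas(grid) ** 2
    if np.any(var == 0.0):
        # degenerate-variance cells: fall back to the density path
        dens = likelihood_over_years(meas, curve, grid)
        if np.any(np.isinf(dens)):
            posterior = np.isinf(dens).astype(float)
            posterior /= posterior.sum()
        else:
            total = dens.sum()
            if total == 0.0 or not np.isfinite(total):
                raise DegenerateLikelihoodError(
                    "calibration likelihood vanishes over the entire prior range"
                )
            posterior = dens / total
        if dens.max() < 1e-20:
            flags += ("no_support",)
    else:
        # log-space normalisation keeps tiny-sigma calibrations stable
        logd = -0.5 * (meas.f14c - mu) ** 2 / var - 0.5 * np.log(2.0 * np.pi * var)
        if logd.max() < np.log(1e-20):
            flags += ("no_support",)
        posterior = np.exp(logd - logd.max())
        posterior /= posterior.sum()

    peak = posterior.max()
    mask = posterior > peak * mode_threshold
    modes = []
    for a, b in _runs(mask):
        p = posterior[a:b + 1]
        modes.append(Mode(
            year_lo=float(grid[a]), year_hi=float(grid[b]),
            mass=float(p.sum()),
            mean=float(np.dot(grid[a:b + 1], p) / p.sum()),
        ))
    modes = tuple(modes)

    if point_rule == "highest-mass":
        # ties broken toward the earlier mode: argmax takes the first maximum
        selected = int(np.argmax([m.mass for m in modes]))
        rule_tag = "highest-mass"
    elif point_rule == "nearest":
        if reference_year is None:
            raise ParameterError("point_rule='nearest' needs a reference_year")
        selected = int(np.argmin([abs(m.mean - reference_year) for m in modes]))
        rule_tag = f"nearest:{reference_year:g}"
    else:
        raise ParameterError(f"unknown point rule {point_rule!r}")

    return CalibrationResult(
        year_grid=grid,
        posterior=posterior,
        modes=modes,
        hpd_68=_hpd_intervals(grid, posterior, HPD_LEVELS[0]),
        hpd_95=_hpd_intervals(grid, posterior, HPD_LEVELS[1]),
        point_estimate=modes[selected].mean,
        point_rule=rule_tag,
        selected_mode=selected,
        flags=flags,
    )


def invert_monotone(target_f14c: float, curve: AtmosphericCurve,
                    limb: tuple[float, float], tol: float = 1e-6) -> float:
    """Unique year where the interpolated curve equals ``target_f14c`` on a limb.

    The curve must be strictly monotone over ``limb`` (checked at the knots
    and endpoints); the root is found by bisection to ``tol`` years.
    """
    lo, hi = float(limb[0]), float(limb[1])
    if not (curve.contains(lo) and curve.contains(hi)) or lo >= hi:
        raise DomainError(f"limb [{lo}, {hi}] not a valid interval in the curve domain")
    knots = curve.year[(curve.year > lo) & (curve.year < hi)]
    pts = np.concatenate([[lo], knots, [hi]])
    vals = curve.values(pts)
    diffs = np.diff(vals)
    if np.all(diffs > 0):
        sign = 1.0
    elif np.all(diffs < 0):
        sign = -1.0
    else:
        raise ParameterError(f"curve is not strictly monotone on [{lo}, {hi}]")
    v_lo, v_hi = float(vals[0]), float(vals[-1])
    v_min, v_max = min(v_lo, v_hi), max(v_lo, v_hi)
    if not (v_min <= target_f14c <= v_max):
        raise DomainError(
            f"target {target_f14c} outside limb value range [{v_min}, {v_max}]"
        )
    a, b = lo, hi
    fa = sign * (float(curve.values(a)) - target_f14c)
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = sign * (float(curve.values(m)) - target_f14c)
        if (fa <= 0) == (fm <= 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)
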