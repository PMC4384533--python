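"""Atmospheric radiocarbon calibration curves.

Above-ground nuclear testing (1955-1963) nearly doubled the atmospheric
14C/12C ratio; the subsequent uptake of CO2 by the oceans and biosphere has
drawn it down roughly exponentially ever since.  A tissue that stops
exchanging carbon with the atmosphere therefore carries an isotopic
timestamp: its fraction-modern value can be matched back against the
atmospheric record to date the year its carbon was fixed.

This module holds the atmospheric record as a tabulated
:class:`AtmosphericCurve` (decimal year, fraction modern F14C, one-sigma
uncertainty), with loading from delimited text, splicing of a pre-bomb
tree-ring segment onto a bomb-pulse segment, linear interpolation, and a
fully synthetic southern-hemisphere-shaped pulse used as a self-contained
test curve.

Conventions
-----------
* Dates are decimal calendar years.  A documented "year of birth" is taken
  as mid-year (YYYY.5); :func:`midyear` performs that mapping.
* Interpolation is piecewise linear in both the value and its sigma, and no
  extrapolation outside the tabulated domain is permitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, ParseError, SpliceError

__all__ = [
    "AtmosphericCurve",
    "load_curve",
    "splice",
    "interpolate",
    "synthetic_bomb_curve",
    "synthetic_bomb_value",
    "midyear",
]


def midyear(year: float) -> float:
    """Map a documented calendar year to its mid-year decimal date (YYYY.5)."""
    return float(np.floor(year)) + 0.5


@dataclass(frozen=True)
class AtmosphericCurve:
    """Tabulated atmospheric fraction-modern record with uncertainties.

    Parameters
    ----------
    year : ndarray
        Strictly increasing decimal calendar years (length >= 2).
    f14c : ndarray
        Fraction modern at each year; all values > 0.
    sigma : ndarray
        One-sigma uncertainty of ``f14c``; all values >= 0.
    label : str
        Free-text provenance, e.g. a hemispheric zone name.
    """

    year: np.ndarray
    f14c: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=float)
        f14c = np.asarray(self.f14c, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "f14c", f14c)
        object.__setattr__(self, "sigma", sigma)
        if not (year.ndim == f14c.ndim == sigma.ndim == 1):
            raise ParseError("curve columns must be one-dimensional")
        if not (len(year) == len(f14c) == len(sigma)):
            raise ParseError("year, f14c and sigma must have equal length")
        if len(year) < 2:
            raise ParseError("a curve needs at least 2 rows")
        if not np.all(np.isfinite(year)) or not np.all(np.isfinite(f14c)) \
                or not np.all(np.isfinite(sigma)):
            raise ParseError("curve contains non-finite values")
        diffs = np.diff(year)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ParseError(
                f"years not strictly increasing at row {i + 1} (year={year[i + 1]!r})"
            )
        if np.any(f14c <= 0):
            raise ParseError("all f14c values must be > 0")
        if np.any(sigma < 0):
            raise ParseError("all sigma values must be >= 0")

    def __len__(self) -> int:
        return len(self.year)

    @property
    def domain(self) -> tuple[float, float]:
        """(first year, last year) covered by the tabulation."""
        return float(self.year[0]), float(self.year[-1])

    def contains(self, t: float) -> bool:
        lo, hi = self.domain
        return lo <= t <= hi

    def values(self, t: np.ndarray) -> np.ndarray:
        """Vectorised linear interpolation of f14c (domain-checked)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(
                f"date outside curve domain [{lo}, {hi}]"
            )
        return np.interp(t, self.year, self.f14c)

    def sigmas(self, t: np.ndarray) -> np.ndarray:
        """Vectorised linear interpolation of the one-sigma column."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(f"date outside curve domain [{lo}, {hi}]")
        return np.interp(t, self.year, self.sigma)


_REQUIRED_COLUMNS = ("year", "f14c", "sigma")


def load_curve(source, label: str = "") -> AtmosphericCurve:
    """Read an atmospheric curve from delimited text.

    The file must carry a header ``year,f14c,sigma`` (comma- or
    tab-delimited, auto-detected); ``#`` lines are ignored.  Rows are sorted
    by year; duplicate years are rejected with the offending year named.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        table = pd.read_csv(source, sep=None, engine="python", comment="#",
                            skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse curve table: {exc}") from exc
    table.columns = [str(c).strip().lower() for c in table.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing required column {col!r}")
    data = {}
    for col in _REQUIRED_COLUMNS:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.index[values.isna() & table[col].notna()]
        if len(bad) or values.isna().any():
            row = int(bad[0]) if len(bad) else int(values.index[values.isna()][0])
            raise ParseError(f"non-numeric value in column {col!r} at data row {row}")
        data[col] = values.to_numpy(dtype=float)
    order = np.argsort(data["year"], kind="stable")
    year = data["year"][order]
    dup = np.flatnonzero(np.diff(year) == 0)
    if len(dup):
        raise ParseError(f"duplicate year {year[dup[0]]!r} in curve table")
    return AtmosphericCurve(year=year, f14c=data["f14c"][order],
                            sigma=data["sigma"][order], label=label)


def splice(prebomb: AtmosphericCurve | None, bomb: AtmosphericCurve,
           boundary_year: float) -> AtmosphericCurve:
    """Join a pre-bomb (tree-ring) segment onto a bomb-pulse segment.

    Pre-bomb points at or after ``boundary_year`` and bomb points before it
    are dropped, so overlapping tabulations splice cleanly.  The result must
    still satisfy the strictly-increasing-year invariant.
    """
    if prebomb is None:
        pre_year = np.empty(0)
        pre_f = np.empty(0)
        pre_s = np.empty(0)
        pre_label = ""
    else:
        keep = prebomb.year < boundary_year
        pre_year, pre_f, pre_s = (prebomb.year[keep], prebomb.f14c[keep],
                                  prebomb.sigma[keep])
        pre_label = prebomb.label
    keep = bomb.year >= boundary_year
    year = np.concatenate([pre_year, bomb.year[keep]])
    f14c = np.concatenate([pre_f, bomb.f14c[keep]])
    sigma = np.concatenate([pre_s, bomb.sigma[keep]])
    if len(year) < 2:
        raise SpliceError("spliced curve has fewer than 2 points")
    if np.any(np.diff(year) <= 0):
        raise SpliceError("spliced year sequence is not strictly increasing")
    label = " + ".join(x for x in (pre_label, bomb.label) if x)
    return AtmosphericCurve(year=year, f14c=f14c, sigma=sigma, label=label)


def interpolate(curve: AtmosphericCurve, t: float):
    """Evaluate the curve at decimal year ``t`` (linear; exact at knots).

    Returns
    -------
    F14CValue
        Interpolated fraction modern with interpolated one-sigma.
    """
    from .ams import F14CValue  # local import avoids a cycle

    if not curve.contains(t):
        lo, hi = curve.domain
        raise DomainError(f"year {t} outside curve domain [{lo}, {hi}]")
    return F14CValue(float(np.interp(t, curve.year, curve.f14c)),
                     float(np.interp(t, curve.year, curve.sigma)))


# ---------------------------------------------------------------------------
# Synthetic southern-hemisphere-shaped bomb pulse (self-contained test curve)
# ---------------------------------------------------------------------------
#
# Three analytic pieces: a slight Suess-effect decline before 1955, a linear
# rise through the weapons-testing decade, and an exponential decline with a
# 16-year e-folding time after the 1965 peak.  Continuous at both joins.

_PREBOMB_LEVEL = 0.980
_SUESS_SLOPE = 0.0002      # per year decline, fossil-fuel CO2 dilution
_RISE_START = 1955.0
_PEAK_YEAR = 1965.0
_RISE_SLOPE = 0.0631       # per year, linear rise 1955-1965
_PEAK_EXCESS = 0.600       # peak F14C is 1.0 + 0.600
_EFOLDING = 16.0           # years, post-peak decline
_FIXTURE_SIGMA = 0.005
_FIXTURE_SPAN = (1900.0, 2000.0)


def synthetic_bomb_value(t):
    """Analytic fraction modern of the synthetic bomb-pulse curve at year ``t``."""
    t = np.asarray(t, dtype=float)
    pre = _PREBOMB_LEVEL - _SUESS_SLOPE * (t - 1900.0)
    rise = (_PREBOMB_LEVEL - _SUESS_SLOPE * (_RISE_START - 1900.0)
            + _RISE_SLOPE * (t - _RISE_START))
    fall = 1.0 + _PEAK_EXCESS * np.exp(-(t - _PEAK_YEAR) / _EFOLDING)
    out = np.where(t < _RISE_START, pre, np.where(t < _PEAK_YEAR, rise, fall))
    return out if out.ndim else float(out)


def synthetic_bomb_curve(grid_step: float = 0.05) -> AtmosphericCurve:
    """Tabulate the synthetic bomb-pulse curve on [1900, 2000].

    Parameters
    ----------
    grid_step : float
        Tabulation step in years, 0 < grid_step <= 1.
    """
    if not (0.0 < grid_step <= 1.0) or not np.isfinite(grid_step):
        raise ParameterError(f"grid_step must be in (0, 1], got {grid_step!r}")
    lo, hi = _FIXTURE_SPAN
    n = (hi - lo) / grid_step
    if abs(n - round(n)) < 1e-9:
        year = np.linspace(lo, hi, int(round(n)) + 1)
    else:
        year = np.append(np.arange(lo, hi, grid_step), hi)
    return AtmosphericCurve(
        year=year,
        f14c=synthetic_bomb_value(year),
        sigma=np.full(len(year), _FIXTURE_SIGMA),
        label="synthetic southern-hemisphere pulse",
    )
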