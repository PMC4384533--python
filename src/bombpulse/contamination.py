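"""Stable-isotope mass balance for contamination checks.

Microgram-scale lipid targets are vulnerable to carbon carried over from
solvents.  Spiking the extraction solvent with 13C-enriched methanol turns
delta13C into a tracer: any solvent carbon retained by the lipid fraction
shifts the measured delta13C of the labelled batch relative to the
unlabelled one, and a two-component mass balance converts that shift into a
carbon weight fraction of contamination.

Mixing is linear in the weight fraction f:

    delta_mix = (1 - f) delta_base + f delta_source

which is the standard approximation to exact isotope-ratio mixing; at the
enrichments involved here the error is below 0.1 permil.  The inverse,
:func:`infer_contamination_fraction`, solves for f with first-order error
propagation.  :func:`contamination_effect_on_f14c` applies the same mass
balance to a radiocarbon value, quantifying how a given contamination level
would bias a fraction-modern measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ams import F14CValue
from .errors import DomainError, ParameterError, TracerError

__all__ = [
    "R_VPDB",
    "DeltaValue",
    "ContaminationEstimate",
    "atom_fraction_to_delta",
    "mix_delta",
    "infer_contamination_fraction",
    "contamination_effect_on_f14c",
]

#: 13C/12C ratio of the VPDB standard.
R_VPDB = 0.0111802


@dataclass(frozen=True)
class DeltaValue:
    """A delta13C measurement (permil vs VPDB) with one-sigma uncertainty."""

    delta13c: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta13c) or self.delta13c <= -1000.0:
            raise ParameterError(
                f"delta13c must be finite and > -1000 permil, got {self.delta13c!r}"
            )
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")


@dataclass(frozen=True)
class ContaminationEstimate:
    """Inferred contaminant carbon weight fraction with one-sigma uncertainty."""

    fraction: float
    sigma: float
    flags: tuple[str, ...] = ()


def atom_fraction_to_delta(atom_fraction_13c: float) -> DeltaValue:
    """Convert a 13C atom fraction to delta13C (permil vs VPDB).

    delta = ((af / (1 - af)) / R_VPDB - 1) * 1000, for af in (0, 1).
    """
    af = float(atom_fraction_13c)
    if not (0.0 < af < 1.0):
        raise DomainError(f"atom fraction must lie in (0, 1), got {af!r}")
    ratio = af / (1.0 - af)
    return DeltaValue((ratio / R_VPDB - 1.0) * 1000.0)


def mix_delta(fraction_contaminant: float, delta_contaminant: DeltaValue,
              delta_base: DeltaValue) -> DeltaValue:
    """Linear mass-balance mixing of a contaminant delta into a base delta."""
    f = float(fraction_contaminant)
    if not (0.0 <= f <= 1.0):
        raise ParameterError(f"mass fraction must lie in [0, 1], got {f!r}")
    value = (1.0 - f) * delta_base.delta13c + f * delta_contaminant.delta13c
    sigma = math.hypot((1.0 - f) * delta_base.sigma, f * delta_contaminant.sigma)
    return DeltaValue(value, sigma)


def infer_contamination_fraction(delta_observed: DeltaValue,
                                 delta_base: DeltaValue,
                                 delta_contaminant: DeltaValue) -> ContaminationEstimate:
    """Carbon weight fraction of contaminant explaining an observed delta shift.

    f = (delta_obs - delta_base) / (delta_source - delta_base); one-sigma by
    first-order propagation over all three deltas.  A negative solution is
    reported as 0 with the ``"negative_clipped"`` flag.
    """
    span = delta_contaminant.delta13c - delta_base.delta13c
    if span == 0.0:
        raise TracerError("contaminant delta equals base delta: tracer is degenerate")
    shift = delta_observed.delta13c - delta_base.delta13c
    f = shift / span
    d_obs = 1.0 / span
    d_base = (delta_observed.delta13c - delta_contaminant.delta13c) / span ** 2
    d_cont = -shift / span ** 2
    sigma = math.sqrt((d_obs * delta_observed.sigma) ** 2
                      + (d_base * delta_base.sigma) ** 2
                      + (d_cont * delta_contaminant.sigma) ** 2)
    if f < 0:
        return ContaminationEstimate(0.0, sigma, ("negative_clipped",))
    return ContaminationEstimate(f, sigma)


def contamination_effect_on_f14c(f14c_true: F14CValue,
                                 fraction_contaminant: float,
                                 f14c_contaminant: F14CValue) -> F14CValue:
    """Fraction modern observed when a weight fraction f of contaminant mixes in.

    f_obs = (1 - f) f_true + f f_cont, with quadrature-propagated sigma.
    """
    f = float(fraction_contaminant)
    if not (0.0 <= f <= 1.0):
        raise ParameterError(f"mass fraction must lie in [0, 1], got {f!r}")
    value = (1.0 - f) * f14c_true.f14c + f * f14c_contaminant.f14c
    sigma = math.hypot((1.0 - f) * f14c_true.sigma, f * f14c_contaminant.sigma)
    return F14CValue(value, sigma, f14c_true.flags)
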