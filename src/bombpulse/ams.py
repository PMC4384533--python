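"""Reduction of raw accelerator mass spectrometry (AMS) measurements.

AMS counts 14C atoms directly in microgram-scale carbon targets.  Turning a
raw isotope-ratio measurement into a fraction-modern value (F14C) involves
three standard steps, all implemented here:

1. :func:`fraction_modern` — normalise the measured ratio for mass-dependent
   fractionation (to delta13C = -25 permil, squared-factor convention) and
   express it relative to 0.95x the fractionation-normalised oxalic-acid-I
   standard activity.
2. :func:`background_correct` — subtract the instrument background measured
   on radiocarbon-free graphite.
3. :func:`blank_mass_correct` — remove the procedural-blank carbon (solvent
   residue carried through extraction) by two-component mass balance.

Uncertainties propagate first order (delta method); a seeded Monte-Carlo
alternative is available for the blank correction.  Where no per-target
counting statistics exist, a per-batch relative precision policy supplies
the measurement sigma (:func:`batch_precision`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CorrectionError, ParameterError, ParseError, ReductionError

__all__ = [
    "F14CValue",
    "AMSRecord",
    "BlankModel",
    "PrecisionPolicy",
    "fraction_modern",
    "background_correct",
    "blank_mass_correct",
    "batch_precision",
    "reduce_record",
    "read_ams_records",
    "read_f14c_table",
    "write_f14c_table",
]

#: Fractionation reference for the sample (permil VPDB).
DELTA13C_REFERENCE = -25.0


@dataclass(frozen=True)
class F14CValue:
    """A fraction-modern measurement with one-sigma uncertainty.

    ``flags`` records non-fatal events (e.g. clipping at zero when a
    background exceeds the raw value).
    """

    f14c: float
    sigma: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.f14c) or self.f14c < 0:
            raise ReductionError(f"f14c must be finite and >= 0, got {self.f14c!r}")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ReductionError(f"sigma must be finite and >= 0, got {self.sigma!r}")


@dataclass(frozen=True)
class AMSRecord:
    """One raw AMS target measurement before reduction.

    ``ratio_sample`` and ``ratio_standard`` are the measured isotope ratios
    (14C/12C or 14C/13C, any common arbitrary units) of the target and of
    the normalisation standard; ``ratio_standard`` is taken as already
    normalised to the oxalic-acid-I reference composition (-19 permil).
    ``machine_background`` is the fraction-modern equivalent measured on
    radiocarbon-free graphite.  ``sigma_ratio_sample``, when present, carries
    the counting-statistics uncertainty of ``ratio_sample``.
    """

    sample_id: str
    ratio_sample: float
    ratio_standard: float
    delta13c: float
    carbon_mass_total: float
    batch_id: str = ""
    machine_background: float = 0.0
    sigma_ratio_sample: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_sample <= 0 or self.ratio_standard <= 0:
            raise ReductionError(
                f"{self.sample_id}: isotope ratios must be > 0"
            )
        if self.carbon_mass_total <= 0:
            raise ReductionError(
                f"{self.sample_id}: carbon_mass_total must be > 0 ug"
            )
        if self.machine_background < 0:
            raise ReductionError(f"{self.sample_id}: machine_background must be >= 0")
        if not (-1000.0 < self.delta13c < 100000.0):
            raise ReductionError(
                f"{self.sample_id}: delta13c {self.delta13c!r} outside (-1000, 100000) permil"
            )


@dataclass(frozen=True)
class BlankModel:
    """Procedural-blank carbon: fraction modern and mass, with uncertainties.

    Blanks are solvent residues carried through the full extraction; the
    plausibility window on the mass (default 0-50 ug) guards against unit
    mistakes, as real procedural blanks here are tens of micrograms.
    """

    f14c_blank: float
    sigma_f_blank: float = 0.0
    mass_blank: float = 0.0
    sigma_mass_blank: float = 0.0
    mass_plausible: tuple[float, float] = (0.0, 50.0)

    def __post_init__(self) -> None:
        for name in ("f14c_blank", "sigma_f_blank", "mass_blank", "sigma_mass_blank"):
            if getattr(self, name) < 0:
                raise ParameterError(f"blank field {name} must be >= 0")
        lo, hi = self.mass_plausible
        if not (lo <= self.mass_blank <= hi):
            raise ParameterError(
                f"blank mass {self.mass_blank} ug outside plausible range [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class PrecisionPolicy:
    """Per-batch relative precision of reduced fraction-modern values.

    The default reflects small-accelerator performance: 0.5% relative for
    targets of at least ``mass_threshold`` (50 ug) carbon, 2% below it.
    ``batch_multipliers`` scales the relative precision per batch id, since
    batches prepared on different CO2 handling lines differ in precision.
    """

    rel_high_mass: float = 0.005
    rel_low_mass: float = 0.02
    mass_threshold: float = 50.0
    batch_multipliers: dict = field(default_factory=dict)

    def multiplier(self, batch_id: str | None) -> float:
        if batch_id is None:
            return 1.0
        return float(self.batch_multipliers.get(batch_id, 1.0))


def fractionation_factor(delta13c: float) -> float:
    """Squared-factor delta13C normalisation to -25 permil: [0.975/(1+d/1000)]^2."""
    return (0.975 / (1.0 + delta13c / 1000.0)) ** 2


def batch_precision(f14c: float, carbon_mass_total: float,
                    policy: PrecisionPolicy | None = None,
                    batch_id: str | None = None) -> float:
    """One-sigma measurement uncertainty from the per-batch precision policy."""
    if policy is None:
        policy = PrecisionPolicy()
    if carbon_mass_total <= 0 or not np.isfinite(carbon_mass_total):
        raise ParameterError(f"carbon mass must be > 0 ug, got {carbon_mass_total!r}")
    rel = (policy.rel_high_mass if carbon_mass_total >= policy.mass_threshold
           else policy.rel_low_mass)
    return abs(f14c) * rel * policy.multiplier(batch_id)


def fraction_modern(rec: AMSRecord,
                    policy: PrecisionPolicy | None = None) -> F14CValue:
    """Reduce a raw AMS record to fraction modern.

    F14C = R_sample * [0.975/(1 + delta13C/1000)]^2 / (0.95 * R_standard)

    where R_standard is the -19-permil-normalised oxalic-acid-I ratio.  The
    uncertainty comes from ``rec.sigma_ratio_sample`` when supplied
    (counting statistics), otherwise from the per-batch precision policy.
    """
    factor = fractionation_factor(rec.delta13c)
    f14c = rec.ratio_sample * factor / (0.95 * rec.ratio_standard)
    if rec.sigma_ratio_sample is not None:
        sigma = f14c * rec.sigma_ratio_sample / rec.ratio_sample
    else:
        sigma = batch_precision(f14c, rec.carbon_mass_total, policy, rec.batch_id)
    return F14CValue(f14c, sigma)


def background_correct(raw: F14CValue, background: F14CValue) -> F14CValue:
    """Subtract the instrument background (radiocarbon-free graphite).

    Linear subtraction with quadrature sigma; a background exceeding the raw
    value clips the result to zero and sets the ``"clipped_at_zero"`` flag.
    """
    value = raw.f14c - background.f14c
    sigma = math.hypot(raw.sigma, background.sigma)
    flags = tuple(dict.fromkeys(raw.flags + background.flags))
    if value < 0:
        return F14CValue(0.0, sigma, flags + ("clipped_at_zero",))
    return F14CValue(value, sigma, flags)


def blank_mass_correct(measured: F14CValue, blank: BlankModel,
                       carbon_mass_total: float,
                       method: str = "delta",
                       n_mc: int = 20000, seed: int = 0) -> F14CValue:
    """Remove procedural-blank carbon by two-component mass balance.

    The combusted target holds ``carbon_mass_total`` ug of which
    ``blank.mass_blank`` ug is blank carbon, so

        f_sample = (f_measured * M_total - f_blank * m_blank) / (M_total - m_blank)

    Uncertainty propagates over (f_measured, f_blank, m_blank) either first
    order (``method="delta"``) or by seeded Monte Carlo (``method="mc"``).
    """
    m_total = float(carbon_mass_total)
    m_blank = blank.mass_blank
    if m_total <= 0:
        raise CorrectionError(f"carbon_mass_total must be > 0 ug, got {m_total!r}")
    if m_blank >= m_total:
        raise CorrectionError(
            f"blank mass {m_blank} ug >= total carbon {m_total} ug: blank dominates"
        )
    m_sample = m_total - m_blank
    value = (measured.f14c * m_total - blank.f14c_blank * m_blank) / m_sample

    if method == "delta":
        d_f_meas = m_total / m_sample
        d_f_blank = -m_blank / m_sample
        d_m_blank = m_total * (measured.f14c - blank.f14c_blank) / m_sample ** 2
        sigma = math.sqrt((d_f_meas * measured.sigma) ** 2
                          + (d_f_blank * blank.sigma_f_blank) ** 2
                          + (d_m_blank * blank.sigma_mass_blank) ** 2)
    elif method == "mc":
        rng = np.random.default_rng(seed)
        f_m = rng.normal(measured.f14c, measured.sigma, n_mc)
        f_b = rng.normal(blank.f14c_blank, blank.sigma_f_blank, n_mc)
        m_b = rng.normal(m_blank, blank.sigma_mass_blank, n_mc)
        m_b = np.clip(m_b, 0.0, m_total * (1 - 1e-9))
        draws = (f_m * m_total - f_b * m_b) / (m_total - m_b)
        sigma = float(np.std(draws, ddof=1))
    else:
        raise ParameterError(f"unknown propagation method {method!r}")

    flags = measured.flags
    if value < 0:
        return F14CValue(0.0, sigma, flags + ("clipped_at_zero",))
    return F14CValue(value, sigma, flags)


def reduce_record(rec: AMSRecord, blank: BlankModel | None = None,
                  policy: PrecisionPolicy | None = None) -> F14CValue:
    """Full reduction chain: normalise, background-correct, blank-correct."""
    raw = fraction_modern(rec, policy)
    raw = background_correct(raw, F14CValue(rec.machine_background, 0.0))
    if blank is not None and blank.mass_blank > 0:
        raw = blank_mass_correct(raw, blank, rec.carbon_mass_total)
    return raw


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_RAW_COLUMNS = ("sample_id", "ratio_sample", "ratio_standard", "delta13c",
                "carbon_mass_total", "batch_id", "machine_background")


def read_ams_records(source) -> list[AMSRecord]:
    """Read raw AMS records from delimited text (header: sample_id,ratio_sample,...)."""
    table = pd.read_csv(source, sep=None, engine="python", comment="#")
    table.columns = [str(c).strip().lower() for c in table.columns]
    for col in _RAW_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing required column {col!r} in AMS file")
    records = []
    for i, row in table.iterrows():
        try:
            records.append(AMSRecord(
                sample_id=str(row["sample_id"]),
                ratio_sample=float(row["ratio_sample"]),
                ratio_standard=float(row["ratio_standard"]),
                delta13c=float(row["delta13c"]),
                carbon_mass_total=float(row["carbon_mass_total"]),
                batch_id=str(row["batch_id"]),
                machine_background=float(row["machine_background"]),
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad AMS record at data row {i}: {exc}") from exc
    return records


def read_f14c_table(source) -> pd.DataFrame:
    """Read a reduced table with columns sample_id,f14c,sigma."""
    table = pd.read_csv(source, sep=None, engine="python", comment="#")
    table.columns = [str(c).strip().lower() for c in table.columns]
    for col in ("sample_id", "f14c", "sigma"):
        if col not in table.columns:
            raise ParseError(f"missing required column {col!r} in reduced file")
    return table


def write_f14c_table(values: dict[str, F14CValue], path) -> None:
    """Write reduced values as sample_id,f14c,sigma delimited text."""
    frame = pd.DataFrame(
        {"sample_id": list(values),
         "f14c": [v.f14c for v in values.values()],
         "sigma": [v.sigma for v in values.values()]}
    )
    frame.to_csv(path, index=False)
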