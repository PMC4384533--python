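# bombpulse

Bomb-pulse radiocarbon birth dating of long-lived biomolecules.

Above-ground nuclear weapons testing (1955–1963) nearly doubled the
atmospheric ¹⁴CO₂ concentration; since the test-ban treaty it has decayed
roughly exponentially through ocean and biosphere uptake. Every calendar
year since 1950 therefore carries a distinct atmospheric fraction-modern
(F¹⁴C) signature. A molecular pool that stops exchanging carbon with the
environment — such as the membrane lipids of the human ocular lens nucleus,
whose fiber cells form *in utero* and are never replaced — keeps the
signature of its formation year. Measuring F¹⁴C in such a pool by
accelerator mass spectrometry (AMS) and inverting it against the
atmospheric record dates the pool's biosynthesis and bounds its turnover
rate.

`bombpulse` is for researchers applying bomb-pulse dating to microgram-scale
biological samples. It implements the full inference chain:

1. **AMS data reduction** (`bombpulse.ams`) — fractionation normalisation to
   δ¹³C = −25‰ against 0.95× the oxalic-acid-I standard activity,
   instrument-background subtraction, and procedural-blank removal by
   two-component mass balance, with first-order (or Monte-Carlo) error
   propagation:
   F¹⁴C = R·[0.975/(1+δ¹³C/1000)]² / (0.95·R_OxI), and
   f_s = (f_m·M − f_b·m_b)/(M − m_b).
2. **Calibration** (`bombpulse.calibration`) — Gaussian likelihood
   L(t) ∝ N(F; μ(t), s² + s_c(t)²) over a calendar-year grid, normalised to
   a posterior under a uniform prior; posterior modes, 68.3%/95.4% HPD
   intervals, and a configurable point estimate. The bomb pulse's rise and
   fall make post-bomb posteriors bimodal; both modes are reported.
3. **Turnover modelling** (`bombpulse.turnover`) — a one-compartment
   first-order exchange model,
   F(T) = e^{−kΔ} F_atm(t₀) + ∫ₜ₀ᵀ k e^{−k(T−u)} F_atm(u) du,
   fitted by profile likelihood with likelihood-ratio confidence intervals
   and a boundary-corrected test of k = 0 (no turnover).
4. **Contamination check** (`bombpulse.contamination`) — stable-isotope mass
   balance converting a δ¹³C shift between batches extracted with labelled
   and unlabelled solvent into a contaminant carbon weight fraction.
5. **Cohort validation** (`bombpulse.cohort`) — a statsmodels-style
   `BirthDateModel` whose `fit()` calibrates every donor and regresses
   predicted on documented birth year; slope ≈ 1, intercept ≈ 0 and high R²
   demonstrate that the pool retains birth-year carbon.
6. **Synthetic data** (`bombpulse.simulate`) — seeded generators for reduced
   and raw-AMS donor cohorts with the study's statistical structure, plus a
   fully synthetic southern-hemisphere-shaped calibration curve, so the
   entire chain is testable offline.

## Worked example

Calibrate a single post-bomb measurement (1.300 ± 0.005) against the
synthetic pulse:

```bash
$ bombpulse calibrate --curve synthetic --f14c 1.300 --sigma 0.005
kind    year_lo year_hi mass    mean
mode    1959.85 1960.65 0.2289  1960.25
mode    1974.75 1977.55 0.7709  1976.10
...
point   1976.10 0.38            highest-mass
```

The value intersects the pulse twice: on the rising limb near 1960.25 and on
the falling limb near 1976.10. The falling-limb mode carries 77% of the
posterior mass (the limb is shallower, so more years are compatible), and
the default point rule selects it: 1976.10 ± 0.38 yr.

A full validation cohort — 23 synthetic donors born 1966–1993, observed
F¹⁴C = atmosphere at birth + 1% Gaussian noise, each calibrated and
regressed against the documented birth year:

```python
import numpy as np
from bombpulse import (BirthDateModel, DonorRecord, F14CValue, PipelineConfig,
                       fit_turnover, synthetic_bomb_curve, synthetic_bomb_value)

curve = synthetic_bomb_curve()
rng = np.random.default_rng(20150311)
births = np.linspace(1966.0, 1993.0, 23)
donors = [
    DonorRecord(f"donor{i:03d}", float(b), 2000.0,
                f14c=F14CValue(float(synthetic_bomb_value(b))
                               + rng.normal(0.0, 0.01), 0.01))
    for i, b in enumerate(births)
]
results = BirthDateModel(donors, curve,
                         PipelineConfig(prior_range=(1900.0, 2000.0))).fit()
print(results.summary())
print(fit_turnover(donors, curve).summary())
```

```
Predicted vs documented birth year
  n         : 23
  slope     : 1.0181 +/- 0.0281
  intercept : -35.97 +/- 55.55 yr
  R^2       : 0.9843
One-compartment turnover fit
  donors                : 23
  k_hat (per yr)        : 0.0001278
  68% CI (per yr)       : [0, 0.00057305]
  95% CI (per yr)       : [0, 0.0010047]
  LRT vs k=0            : 0.08349
  one-sided p (k=0)     : 0.3863
```

The regression slope is statistically indistinguishable from one and the
intercept from zero: each donor's lipid F¹⁴C predicts their birth year. The
turnover fit on the same cohort bounds the exchange rate below ~0.001/yr
(95% CI) and does not reject k = 0 — no detectable turnover.

The same pipeline runs from the shell (`bombpulse simulate`,
`bombpulse cohort`, `bombpulse turnover-fit`, `bombpulse contamination`);
see `bombpulse --help`.

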