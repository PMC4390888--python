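# superfill

Statistics and kinetics of macromolecule entrapment in micrometre-sized
lipid vesicles.

When lipid vesicles form spontaneously in a solution of dissolved
macromolecules, how many molecules does each vesicle capture?  The null
expectation is simple: a vesicle of volume *V* closing in a solution of
bulk concentration *C* encloses on average μ = *N*<sub>A</sub>·*C*·*V*
molecules, with Poisson (≈ Gaussian, for μ of a few tens) fluctuations
of order √μ.  Confocal fluorescence experiments on 1–2 μm vesicles tell
a different story: a small subpopulation (&lt;1–2%) is "super-filled",
with internal concentrations 2–4× the bulk (occasionally &gt;10×) — an
outcome the Gaussian null puts at probabilities of 10⁻⁸ and below — and
occupancy histograms that resemble a power law *f*(*n*) ∝ *n*^(−a)
rather than a Poisson curve.  Because reaction rates follow enzyme
concentration, super-filled vesicles are also micro-reactors: their
lumen converts substrate faster than the surrounding bulk.

The package is aimed at researchers modelling protocell
compartmentalization or quantifying vesicle-encapsulation experiments.
It provides:

- **`geometry`** — spherical-vesicle arithmetic: volume/area, expected
  occupancy μ = *N*<sub>A</sub>·*C*·*V*, lipids per vesicle, vesicle
  number concentration.
- **`entrapment`** — Poisson/Gaussian null models and the power-law
  alternative: exceedance probabilities *P*(*N* &gt; *r*·*N*₀), critical
  concentration factors, co-entrapment product rule (log10-stable down
  to 10⁻³⁰ and far beyond), seeded samplers, and a truncated discrete
  maximum-likelihood power-law fitter.
- **`kinetics`** — the Michaelis–Menten rate-enhancement calculus and a
  deterministic two-compartment simulator: one vesicle per "unitary"
  volume of bulk, membrane-permeable substrate
  (flux *P*·*A*·ΔS), impermeable fluorescent product, plus the
  co-encapsulation variant (impermeable macromolecular substrate) and a
  closed-form linear oracle for validation.  The observable is
  *r*<sub>V</sub>, the in/out slope ratio of product accumulation.
- **`synthetic`** — a ground-truthed confocal-microscopy emulator:
  log-normal vesicle diameters (1.3 ± 0.6 μm), a configurable
  super-filled subpopulation with skewed *r*<sub>F</sub>, linear 8-bit
  calibration, PSF blur, shot and read noise, TIFF/CSV/JSON fixtures.
- **`analysis`** — the measurement pipeline: robust background
  *F*₀ estimation, bright-vesicle detection at *F*₀ + *k*·SD, PSF-aware
  *r*<sub>F</sub> = *F*/*F*₀ and diameter measurement, distribution
  summaries (skewness, normal vs log-normal fits), and slope/intercept
  time-course analysis yielding *r*<sub>V</sub> in intensity units.
- **`cli`** — `superfill` command with subcommands
  (`gaussian-table`, `rate-enhancement`, `simulate-kinetics`,
  `entrapment-stats`, `generate-synthetic`, `analyze-frames`,
  `recover-params`), each writing a manifest with seed and checksums.

## Worked example

```python
import math
import superfill as sf

# How many molecules does a 1 um vesicle capture from 0.1 uM solution?
mu = sf.expected_occupancy(sf.SoluteSpec("bsa-fitc", 0.1e-6), sf.VesicleSpec(1.0))
print(f"expected occupancy mu = {mu:.1f}  (dN = {math.sqrt(mu):.1f})")

# How likely are internal concentrations r times the expected one?
print(sf.gaussian_table(sf.GaussianFluctuationModel(32, 5.6)).to_string(index=False))

# What slope ratio r_V does an enzyme-partitioning ratio produce?
for r in (0.33, 1.0, 3.0):
    trace = sf.simulate_two_compartment(sf.TwoCompartmentConfig(r_enzyme=r))
    res = sf.extract_rate_ratio(trace)
    print(f"r_enzyme = {r:<4}  r_V = {res.r_v:.2f}  lag = {res.lag:.0f} s")
```

prints

```
expected occupancy mu = 31.5  (dN = 5.6)
   r  threshold_count  tail_probability  tail_percent  log10_tail_percent
1.00            32.00      5.000000e-01  5.000000e+01            1.698970
1.41            45.12      9.568354e-03  9.568354e-01           -0.019163
2.00            64.00      5.508289e-09  5.508289e-07           -6.258983
2.40            76.80      6.220961e-16  6.220961e-14          -13.206143
r_enzyme = 0.33  r_V = 0.28  lag = 86 s
r_enzyme = 1.0   r_V = 0.80  lag = 84 s
r_enzyme = 3.0   r_V = 2.17  lag = 77 s
```

Reading the output: a 1 μm vesicle in 0.1 μM solution captures ~32
molecules with fluctuation ~5.6, so 99% of passively filled vesicles
concentrate by less than a factor 1.41, a factor 2 has probability
~5×10⁻⁷ % and a factor 2.4 is essentially nil (10⁻¹³ %) — observed
super-filled frequencies of 0.1–1% at *r* = 2–4 are therefore
incompatible with the null.  In the kinetic simulation the slope ratio
*r*<sub>V</sub> tracks the enzyme-partitioning ratio (0.28 for 0.33,
2.17 for 3) with a lag of a minute or two from membrane permeation:
measuring *r*<sub>V</sub> optically estimates how concentrated the
enzyme is inside the vesicles.

The same numbers are available from the shell:

```bash
superfill gaussian-table --n0 32 --delta-n 5.6 --out out/
superfill simulate-kinetics --config examples/kinetics.json --out out/
```

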