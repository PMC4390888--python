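# Methods

This note documents the models implemented in `superfill`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Units and geometry

One internal unit convention is used throughout, owned by
`superfill.units`: lengths in μm, volumes in fL (1 μm³ = 1 fL),
areas in μm², concentrations in mol/L, time in s, permeability quoted
in cm/s.  Vesicles are treated as unilamellar spheres; lamellarity,
non-spherical shapes and bilayer thermodynamics are out of model.  The
lipids-per-vesicle count uses an area per lipid of 0.72 nm² by default
— the standard fluid-phase phosphatidylcholine value — with two
leaflets; it is configurable and should be set explicitly for other
membrane compositions.  With this assumption, 1 μM lipid assembled
into 1 μm vesicles gives ~6.9×10⁷ vesicles/mL, so a 0.1% subpopulation
numbers ~10⁵ per mL (order of magnitude only; no specific area per
lipid should be read as an experimental determination).

## Occupancy models

**Poisson null.**  Entrapment at membrane closure of a well-mixed
solution: occupancy N ~ Poisson(μ), μ = N_A·C·V.  pmf and tail
computations go through scipy in log space and are usable up to
μ ~ 10⁶; summed pmf accuracy at that extreme is limited by the pmf
evaluation itself (~10⁻⁹), not by overflow.

**Gaussian fluctuation model.**  For μ of a few tens the Poisson is
locally well approximated by N(N₀, ΔN²) with ΔN = √N₀.  The exceedance
P(N > r·N₀) is computed with the complementary error function and, for
values beyond double underflow, reported as log10 via `log_ndtr`.  The
factor-2 agreement between Poisson and Gaussian tails is a *local*
statement: it holds for r ≤ 1.5 at N₀ ≈ 30–50 (the regime of interest,
N₀ ≈ 32) and degrades for much larger N₀, where deep relative tails
are governed by large-deviation corrections the normal approximation
does not capture.

**Reporting convention.**  Exceedance tables can be produced either
from pinned rounded moments (N₀ = 32, ΔN = 5.6) or from the unrounded
μ = 31.5; the two differ visibly in the threshold column (r = 1.41
gives 45.1 vs 44.6).  Both are supported; the critical-factor
computation uses whatever moments the caller supplies.

**Power law.**  The empirical alternative f(n) ∝ n^(−a) is implemented
as a truncated discrete power law on [n_min, n_max] mixed with an
explicit probability mass at n = 0, because empty vesicles dominate
real populations while n^(−a) is undefined at zero.  The truncation
keeps the distribution proper for a ≤ 1; the default n_max = 10⁶ is a
generous stand-in for the physical packing ceiling of the lumen (a
true close-packing bound depends on the solute's size, which the
occupancy model deliberately does not carry — set n_max from geometry
when it matters).  No default exponent is claimed to be an
experimental value.

**Fitting.**  The exponent is estimated by maximizing the truncated
discrete log-likelihood (bounded Brent search, 10⁻⁸ tolerance on a),
not by least squares on a log-log histogram, which is biased and has
no valid error model.  The standard error comes from the observed
information, which for this one-parameter exponential family equals
N·Var_model[log n].  Recovery of a ∈ {1.2, 1.5, 2.0} within 3 SE is
verified on seeded samples of n = 10⁴.

**Co-entrapment.**  Independence across species gives
P = Π_i P(N_i ≥ k_i); the product is accumulated as a sum of Poisson
log-survival values, so probabilities of order 10⁻³⁰ and far smaller
are exact in the log10 field while the linear field underflows
gracefully to 0.

## Two-compartment kinetics

The enzymatic experiment — enzyme both in bulk and inside vesicles, a
membrane-permeable substrate added outside — is modelled per vesicle:
each liposome (default d = 1.3 μm, V_in = 1.15 fL) owns a "unitary"
share of the sample, default 50 fL, whose remainder V_out = 48.85 fL
is the bulk compartment.  State variables are the four concentrations
(substrate and product, in and out):

    dS_out/dt = −v(E_out, S_out) − J/V_out      J = P·A·(S_out − S_in)
    dS_in/dt  = +J/V_in − v(E_in, S_in)         v(E,S) = k_cat·E·S/(K_M+S)
    dP_out/dt = +v(E_out, S_out)
    dP_in/dt  = +v(E_in, S_in)

Assumptions: enzyme is a non-depleting catalyst at fixed concentration
(E_in = r_enzyme·E_out); substrate hydrolysis is a single-step
Michaelis–Menten conversion; the fluorescent product cannot cross the
membrane (efflux is a flag for sensitivity analysis, default off);
vesicle uptake depletes its own 50 fL of bulk (mole conservation
holds across the pair); vesicles do not interact.  Default constants
are the carbonic anhydrase / CFDA values (K_M = 4.0 mM,
k_cat = 3.0 s⁻¹, P = 10⁻⁷ cm/s, E_out = 0.5 μM, S_out(0) = 80 μM) and,
for the co-encapsulation variant, the proteinase K / BSA-FITC values
(K_M = 2.3 mM, k_cat = 1 s⁻¹) with J ≡ 0 and
S_in(0) = r_substrate·S_out(0).

Integration uses LSODA (stiff-capable — at P = 10⁻² cm/s the exchange
rate is ~460 s⁻¹ against catalytic rates of 10⁻⁴ s⁻¹) with
rtol = 10⁻⁹, atol = 10⁻¹⁵ mol/L, output sampled every second over a
30 min horizon.  Tightening tolerances or halving the output step
moves r_V by < 0.5%.

**Rate-enhancement calculus.**  Concentrating enzyme by f_E and
substrate by f_S changes the initial rate by
f_E·f_S·(1+s₁)/(1+f_S·s₁), s₁ = S₁/K_M; for f_S = 1 this is exactly
f_E at any substrate level, and f_E = f_S = 3 from s₁ = 1/2 gives 5.4.

**Slope ratio r_V.**  Product time courses are fitted by ordinary
least squares over a common window and r_V = slope_in/slope_out.
The "quasi-linear region" is genuinely a free choice, and r_V depends
on it: the default window is the first half of the trace,
[0, t_end/2].  Rationale: over the second half the bulk reaction has
consumed enough substrate (~50% at the default parameters) that both
curves bend, and a late window systematically inflates r_V (the
lumen, fed through the membrane, lags the depletion); the early
window precedes depletion, and the permeation lag it contains
(time constant V_in/(P·A) ≈ 3.6 min at defaults) is absorbed into the
fitted intercept and reported separately as the time-axis intercept
("lag", floored at 0).  With this rule the reference configuration
yields r_V = 0.275/0.804/2.174 for enzyme ratios 0.33/1/3.  The
window is a parameter everywhere it is used.

**Linear oracle.**  For S ≪ K_M the rate law is linear,
v ≈ (k_cat/K_M)·E·S, and the four-species system has a constant
generator whose matrix exponential propagates the exact solution at
the output step.  The linearization error is itself of order S/K_M,
so the simulator and oracle agree to ~5×10⁻⁴ at S(0) = K_M/10³ and to
~5×10⁻⁶ at S(0) = K_M/10⁵; the 10⁻⁴-level equivalence check is run at
the latter.  The oracle enforces S(0) ≤ K_M/100.

## Synthetic microscopy

The generator emulates the confocal entrapment experiment so that the
analysis pipeline can be validated against known ground truth:

- **Diameters**: log-normal, moment-matched to mean 1.3 μm and
  SD 0.6 μm, truncated to 0.4–6 μm (the truncation shifts the mean by
  ~0.5%).
- **Super-filled subpopulation**: a fraction (default 1%) gets an
  internal/external concentration ratio r_F drawn from a log-normal
  (default mean 3.5, SD 1.5 — skewed, like the protein solutes) or a
  normal (like the dextran case), truncated at 1; all other vesicles
  sit at exactly the bulk concentration and are invisible against the
  background (no sub-background depletion is modelled).
- **Calibration**: linear concentration → 8-bit intensity with zero
  intercept by default, because a non-zero instrumental offset breaks
  the identity F/F₀ = C_in/C_out that r_F relies on; the default
  places the bulk at intensity 40, so the 255 ceiling corresponds to
  r_F ≈ 6.4 and brighter lumina saturate (flagged).
- **Rendering**: each vesicle is a uniform disk at its great-circle
  diameter (the same 0.9 μm optical-section proxy the measurement
  uses; no partial-volume correction), on a uniform background, then
  Gaussian PSF blur (σ = 0.2 μm), Poisson shot noise (5 photons per
  intensity unit), Gaussian read noise (SD 1), and 8-bit quantization.
  Default raster 512×512 at 0.2 μm/px.
- **Kinetic series**: frame backgrounds follow product_out(t) of a
  simulated trace and lumina follow product_in(t); the proteinase-K
  emulation scales fluorescence by 1 + (13−1)·digested_fraction
  (complete digestion dequenches the label ~13-fold).
- Centres are placed without overlap by seeded dart throwing (grid
  lookup, so 10⁴+ vesicles place in under a second); successive frames
  sample fresh vesicles, since individual vesicles cannot be tracked.

What the generator does **not** emulate: 3-D sectioning and
partial-volume effects, vesicle drift and bleaching, optical
aberrations beyond a Gaussian PSF, aggregates, multi-channel imaging
(a membrane-dye channel exists only as plumbing).  Pipeline tests on
these images therefore validate the measurement logic and its
statistical behaviour, not robustness to real-microscope artifacts.

## Measurement pipeline

Background F₀ is the median of pixels below the 95th intensity
percentile (insensitive to ≤5% bright-pixel contamination) with SD
from the MAD; a frame ≥50% saturated is rejected.  Detection takes
8-connected components above F₀ + k·SD (k = 3) with a minimum area of
a 0.5 μm disk.  Only vesicles brighter than background are detectable
— by construction about the super-filled fraction, and ≤2% under the
default configuration.

Measuring r_F from a thresholded ROI needs care: the PSF inflates the
mask ~2σ past the true edge, and the rim pixels lie between threshold
and lumen level, so a plain (or 1-px-eroded) mask mean underestimates
r_F by 25–30% at the default optics.  The implementation therefore
averages over a central core (half the PSF-deflated radius, ≥1 px),
where the blurred profile is at its plateau, and deflates the
equivalent-circle radius by the erfc edge-profile offset at which the
rim crosses the threshold — both corrections use only the known PSF
width and the detection threshold.  With them, a clean d = 1.3 μm
vesicle at r_F = 5 measures 4.9 and 1.28 μm, and the end-to-end
pipeline (10⁴ vesicles across 50 frames) recovers the super-filled
mean r_F with a residual −8% bias (small-vesicle blur and saturation
clipping), well within the 20% acceptance band.  r_F is a ratio and is
invariant to rescaling the frame intensity when F₀ is re-estimated; it
is *not* invariant to adding an offset, which is exactly why the
calibration default has none.

Time-course analysis fits straight lines to vesicle and background
intensity series over a common window and reports slope ratio (r_V),
intercept ratio (a measure of initial internal over-concentration of
the fluorescent species), and lag — the same contract as the
concentration-space extraction, linked by calibration linearity.

## Problem sizes in the test suite

Simulations are sized for a single CPU: occupancy samplers at 10⁴–10⁵
draws, the Monte-Carlo Gaussian-tail check at 10⁷ draws, power-law
recovery at n = 10⁴ per exponent, model-comparison replicates 100×10⁴,
and the end-to-end imaging pipeline at 10⁴ vesicles over fifty
512×512 frames.  The full suite runs in well under a minute.

## Known limitations

- Deterministic kinetics only: at the default 1.15 fL and ≥0.5 μM a
  lumen holds hundreds of enzyme copies, so ODEs suffice; single-digit
  occupancies would need a stochastic treatment.
- No mechanism for *why* super-filling occurs is modelled; the power
  law is a description, not an explanation.
- The analysis pipeline assumes the generator's optics (Gaussian PSF
  of known width); applying it to real frames requires measuring the
  PSF first.
- r_V depends on the slope window; comparisons are only meaningful
  with the window stated, which the result object always carries.
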