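"""Two-compartment Michaelis-Menten kinetics with membrane permeation.

Models the enzymatic experiment in which catalytically active enzyme is
present both in bulk and inside vesicles: each vesicle is coupled to its
share of the sample (a "unitary volume", default 50 fL holding one
1.3 um liposome).  A membrane-permeable substrate enters the lumen with
flux ``J = P * A * (S_out - S_in)`` and is converted in each compartment
by Michaelis-Menten kinetics into a fluorescent product that, by
default, cannot cross the membrane.  The observable is ``r_V``, the
ratio of the product-accumulation slopes inside vs outside over a
quasi-linear window — an optical proxy for the internal/external enzyme
concentration ratio.

The module also covers the co-encapsulation variant (impermeable
macromolecular substrate enclosed together with the enzyme, the two
compartments evolving independently) and a closed-form linearized
oracle valid when S << K_M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.integrate import solve_ivp

from .geometry import VesicleSpec
from .units import cm_per_s_to_um_per_s

__all__ = [
    "MMParams",
    "PermeationParams",
    "TwoCompartmentConfig",
    "KineticTrace",
    "RateRatioResult",
    "CA_CFDA_MM",
    "PROTEINASE_K_MM",
    "CFDA_PERMEABILITY_CM_S",
    "mm_rate",
    "rate_enhancement_factor",
    "simulate_two_compartment",
    "simulate_coencapsulation",
    "coencapsulation_config",
    "fit_linear_window",
    "extract_rate_ratio",
    "analytic_linear_oracle",
]


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten constants: k_cat (1/s) and K_M (mol/L)."""

    k_cat: float
    K_M: float

    def __post_init__(self) -> None:
        if self.k_cat <= 0 or self.K_M <= 0:
            raise ValueError("k_cat and K_M must be positive")


#: Carbonic anhydrase acting on carboxyfluorescein diacetate
#: (apparent constants: K_M = 4.0 mM, k_cat = 3.0 /s).
CA_CFDA_MM = MMParams(k_cat=3.0, K_M=4.0e-3)

#: Proteinase K digesting FITC-labelled serum albumin
#: (apparent constants: K_M ~ 2.3 mM, k_cat ~ 1 /s).
PROTEINASE_K_MM = MMParams(k_cat=1.0, K_M=2.3e-3)

#: Literature permeability of CFDA across a phosphatidylcholine bilayer.
CFDA_PERMEABILITY_CM_S = 1e-7


@dataclass(frozen=True)
class PermeationParams:
    """Membrane transport: permeability coefficient (cm/s) and which
    species may cross.  The fluorescent product is retained by default
    (carboxyfluorescein permeability is negligible on the experiment's
    timescale)."""

    permeability: float = CFDA_PERMEABILITY_CM_S
    substrate_permeable: bool = True
    product_permeable: bool = False

    def __post_init__(self) -> None:
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")


@dataclass(frozen=True)
class TwoCompartmentConfig:
    """Full parameterization of one bulk + lumen simulation.

    Defaults reproduce the carbonic anhydrase / CFDA setup: 0.5 uM
    external enzyme, 80 uM external substrate, one d = 1.3 um vesicle
    per 50 fL unitary volume, 30 min horizon sampled every second.
    ``r_enzyme`` = [E]_in/[E]_out; ``r_substrate`` (co-encapsulation
    only) sets S_in(0) = r_substrate * S_out(0).
    """

    unitary_volume: float = 50.0  # fL
    vesicle: VesicleSpec = field(default_factory=lambda: VesicleSpec(1.3))
    enzyme_out: float = 0.5e-6  # mol/L
    r_enzyme: float = 1.0
    substrate_out_0: float = 80e-6  # mol/L
    substrate_in_0: float = 0.0
    r_substrate: float | None = None
    mm: MMParams = CA_CFDA_MM
    permeation: PermeationParams = field(default_factory=PermeationParams)
    t_end: float = 1800.0  # s
    output_step: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.unitary_volume <= self.vesicle.volume:
            raise ValueError("unitary_volume must exceed the vesicle volume")
        for name in ("enzyme_out", "substrate_out_0", "substrate_in_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_enzyme < 0:
            raise ValueError("r_enzyme must be >= 0")
        if self.t_end <= 0 or self.output_step <= 0:
            raise ValueError("t_end and output_step must be positive")

    @property
    def volume_out(self) -> float:
        """Bulk share of the unitary volume, fL."""
        return self.unitary_volume - self.vesicle.volume

    @property
    def enzyme_in(self) -> float:
        return self.r_enzyme * self.enzyme_out

    @property
    def permeation_rate_fl_s(self) -> float:
        """P*A in fL/s (volumetric exchange rate across the membrane)."""
        p_um_s = cm_per_s_to_um_per_s(self.permeation.permeability)
        return p_um_s * self.vesicle.membrane_area


@dataclass
class KineticTrace:
    """Time-resolved concentrations (mol/L) in both compartments."""

    time: np.ndarray
    substrate_out: np.ndarray
    substrate_in: np.ndarray
    product_out: np.ndarray
    product_in: np.ndarray
    config: TwoCompartmentConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("substrate_out", "substrate_in", "product_out", "product_in"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")

    def total_moles(self) -> np.ndarray:
        """V_out*(S_out + P_out) + V_in*(S_in + P_in), in mol * fL / L.

        Constant along any closed trace (no synthesis or degradation,
        only conversion and transport)."""
        cfg = self.config
        if cfg is None:
            raise ValueError("trace has no attached config")
        return cfg.volume_out * (self.substrate_out + self.product_out) + (
            cfg.vesicle.volume * (self.substrate_in + self.product_in)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, species, compartment, concentration."""
        blocks = []
        for species, comp, series in (
            ("substrate", "out", self.substrate_out),
            ("substrate", "in", self.substrate_in),
            ("product", "out", self.product_out),
            ("product", "in", self.product_in),
        ):
            blocks.append(
                pd.DataFrame(
                    {
                        "time_s": self.time,
                        "species": species,
                        "compartment": comp,
                        "concentration_M": series,
                    }
                )
            )
        return pd.concat(blocks, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RateRatioResult:
    """Straight-line summaries of a product time course.

    ``r_v = slope_in / slope_out`` over a common fit window;
    ``intercept_ratio`` is reported when the outside intercept is
    positive; ``lag`` is the time-axis intercept of the inside fit,
    floored at zero.
    """

    slope_in: float
    slope_out: float
    intercept_in: float
    intercept_out: float
    r_v: float
    intercept_ratio: float
    lag: float
    fit_window: tuple[float, float]
    r_squared_in: float
    r_squared_out: float


def mm_rate(enzyme: float, substrate: float, mm: MMParams) -> float:
    """Michaelis-Menten rate v = k_cat * E * S / (K_M + S), mol/L/s."""
    if enzyme < 0 or substrate < 0:
        raise ValueError("enzyme and substrate must be >= 0")
    if enzyme == 0.0 or substrate == 0.0:
        return 0.0
    return mm.k_cat * enzyme * substrate / (mm.K_M + substrate)


def rate_enhancement_factor(
    f_e: float, f_s: float, s1_over_km: float | None = None
) -> float:
    """Initial-rate ratio v2/v1 when enzyme and substrate are scaled.

    With E2 = f_e*E1 and S2 = f_s*S1, the Michaelis-Menten ratio is
    ``f_e * f_s * (1 + s1) / (1 + f_s*s1)`` where s1 = S1/K_M.  When the
    substrate is unchanged (f_s = 1) the ratio is exactly f_e,
    independent of s1 — concentrating the enzyme three-fold enhances the
    initial rate three-fold at any substrate level.  Concentrating both
    three-fold from S1 = K_M/2 gives 5.4.
    """
    if f_e < 0 or f_s < 0:
        raise ValueError("scaling factors must be >= 0")
    if f_s == 1.0:
        return f_e
    if s1_over_km is None or s1_over_km <= 0:
        raise ValueError("s1_over_km must be positive when f_s != 1")
    s1 = s1_over_km
    return f_e * f_s * (1.0 + s1) / (1.0 + f_s * s1)


def _rhs(cfg: TwoCompartmentConfig):
    v_out = cfg.volume_out
    v_in = cfg.vesicle.volume
    pa_s = cfg.permeation_rate_fl_s if cfg.permeation.substrate_permeable else 0.0
    pa_p = cfg.permeation_rate_fl_s if cfg.permeation.product_permeable else 0.0
    e_out, e_in = cfg.enzyme_out, cfg.enzyme_in
    kcat, km = cfg.mm.k_cat, cfg.mm.K_M

    def f(t, y):
        s_out, s_in, p_out, p_in = y
        vo = kcat * e_out * s_out / (km + s_out) if s_out > 0 else 0.0
        vi = kcat * e_in * s_in / (km + s_in) if s_in > 0 else 0.0
        j_s = pa_s * (s_out - s_in)  # fL/s * mol/L = 1e-15 mol/s
        j_p = pa_p * (p_out - p_in)
        return (
            -vo - j_s / v_out,
            j_s / v_in - vi,
            vo - j_p / v_out,
            j_p / v_in + vi,
        )

    return f


def simulate_two_compartment(
    config: TwoCompartmentConfig,
    rtol: float = 1e-9,
    atol: float = 1e-15,
) -> KineticTrace:
    """Integrate the bulk + lumen system and sample it at output_step.

    Uses a stiff-capable integrator (LSODA): the well-mixed limit
    (large P) makes the exchange term fast relative to catalysis.
    """
    f = _rhs(config)
    t_eval = np.arange(0.0, config.t_end + 0.5 * config.output_step, config.output_step)
    y0 = (config.substrate_out_0, config.substrate_in_0, 0.0, 0.0)
    sol = solve_ivp(
        f,
        (0.0, config.t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"kinetic integration failed: {sol.message}")
    return KineticTrace(
        time=sol.t,
        substrate_out=sol.y[0],
        substrate_in=sol.y[1],
        product_out=sol.y[2],
        product_in=sol.y[3],
        config=config,
    )


def coencapsulation_config(
    r_enzyme: float,
    r_substrate: float,
    enzyme_out: float = 1.0e-6,
    substrate_out_0: float = 2.5e-6,
    mm: MMParams = PROTEINASE_K_MM,
    **kwargs,
) -> TwoCompartmentConfig:
    """Config for the co-encapsulated protease + macromolecular substrate.

    Both species are enclosed at vesicle formation; the substrate cannot
    cross the membrane, so the two compartments react independently.
    Defaults mirror the proteinase K (1 uM) / BSA-FITC (2.5 uM) assay.
    """
    return TwoCompartmentConfig(
        enzyme_out=enzyme_out,
        r_enzyme=r_enzyme,
        substrate_out_0=substrate_out_0,
        substrate_in_0=r_substrate * substrate_out_0,
        r_substrate=r_substrate,
        mm=mm,
        permeation=PermeationParams(
            permeability=0.0, substrate_permeable=False, product_permeable=False
        ),
        **kwargs,
    )


def simulate_coencapsulation(config: TwoCompartmentConfig, **solver_kwargs) -> KineticTrace:
    """Simulate the co-encapsulation variant (no substrate flux).

    Requires an impermeable substrate and an explicit r_substrate; the
    initial lumen substrate is r_substrate times the bulk one.
    """
    if config.permeation.substrate_permeable:
        raise ValueError("co-encapsulation requires substrate_permeable=False")
    if config.r_substrate is None:
        raise ValueError("co-encapsulation requires r_substrate")
    expected_in0 = config.r_substrate * config.substrate_out_0
    if not math.isclose(config.substrate_in_0, expected_in0, rel_tol=1e-12):
        config = replace(config, substrate_in_0=expected_in0)
    return simulate_two_compartment(config, **solver_kwargs)


def fit_linear_window(
    trace: KineticTrace,
    species: str,
    window: tuple[float, float],
) -> tuple[float, float, float]:
    """OLS straight line to one concentration series over a time window.

    Returns (slope, intercept, R^2).  ``species`` is one of
    substrate_out/substrate_in/product_out/product_in.
    """
    series = getattr(trace, species, None)
    if series is None:
        raise ValueError(f"unknown species {species!r}")
    t0, t1 = window
    if t0 < trace.time[0] - 1e-9 or t1 > trace.time[-1] + 1e-9:
        raise ValueError(f"window {window} outside trace [{trace.time[0]}, {trace.time[-1]}]")
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 3:
        raise ValueError("window must contain at least 3 samples")
    t, y = trace.time[mask], series[mask]
    if np.allclose(y, y[0]):
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def default_fit_window(trace: KineticTrace) -> tuple[float, float]:
    """Default quasi-linear window: the first half of the trace.

    The early part of the run, before substrate depletion in the bulk
    bends the product curves, is where both compartments are closest to
    linear; the permeation lag is absorbed into the fitted intercept
    (and reported as ``lag``).
    """
    return (float(trace.time[0]), float(trace.time[0] + (trace.time[-1] - trace.time[0]) / 2.0))


def extract_rate_ratio(
    trace: KineticTrace,
    window: tuple[float, float] | None = None,
) -> RateRatioResult:
    """Fit product_in and product_out over a common window; form r_V.

    r_V = slope_in/slope_out mirrors, through the retarding membrane,
    the enzyme concentration ratio [E]_in/[E]_out.
    """
    if window is None:
        window = default_fit_window(trace)
    s_in, b_in, r2_in = fit_linear_window(trace, "product_in", window)
    s_out, b_out, r2_out = fit_linear_window(trace, "product_out", window)
    if s_out == 0.0:
        raise ZeroDivisionError("external product slope is zero; r_V undefined")
    lag = max(0.0, -b_in / s_in) if s_in != 0.0 else 0.0
    intercept_ratio = b_in / b_out if b_out > 0 else float("nan")
    return RateRatioResult(
        slope_in=s_in,
        slope_out=s_out,
        intercept_in=b_in,
        intercept_out=b_out,
        r_v=s_in / s_out,
        intercept_ratio=intercept_ratio,
        lag=lag,
        fit_window=window,
        r_squared_in=r2_in,
        r_squared_out=r2_out,
    )


def analytic_linear_oracle(config: TwoCompartmentConfig) -> KineticTrace:
    """Closed-form trace in the first-order regime S << K_M.

    With v = (k_cat/K_M) * E * S the four-species system is linear with
    constant coefficients; the trace is propagated exactly at the output
    step through the matrix exponential of the generator.  Valid (and
    enforced) only when S_out(0) <= K_M / 100.
    """
    if config.substrate_out_0 > config.mm.K_M / 100.0:
        raise ValueError("linear oracle requires S_out_0 <= K_M/100")
    k_out = config.mm.k_cat * config.enzyme_out / config.mm.K_M
    k_in = config.mm.k_cat * config.enzyme_in / config.mm.K_M
    pa = config.permeation_rate_fl_s if config.permeation.substrate_permeable else 0.0
    a_out = pa / config.volume_out
    a_in = pa / config.vesicle.volume
    # state: (S_out, S_in, P_out, P_in); product efflux not supported here
    gen = np.array(
        [
            [-k_out - a_out, a_out, 0.0, 0.0],
            [a_in, -k_in - a_in, 0.0, 0.0],
            [k_out, 0.0, 0.0, 0.0],
            [0.0, k_in, 0.0, 0.0],
        ]
    )
    t = np.arange(0.0, config.t_end + 0.5 * config.output_step, config.output_step)
    step = linalg.expm(gen * config.output_step)
    y = np.empty((len(t), 4))
    y[0] = (config.substrate_out_0, config.substrate_in_0, 0.0, 0.0)
    for i in range(1, len(t)):
        y[i] = step @ y[i - 1]
    return KineticTrace(
        time=t,
        substrate_out=y[:, 0],
        substrate_in=y[:, 1],
        product_out=y[:, 2],
        product_in=y[:, 3],
        config=config,
    )
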