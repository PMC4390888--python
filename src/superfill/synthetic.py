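"""Synthetic confocal-microscopy data with known ground truth.

Emulates the fluorescence-entrapment experiment: a population of
micrometre-sized vesicles (log-normal-like diameters, mean 1.3 um,
SD 0.6 um) suspended in a fluorescent solute solution.  Most vesicles
enclose solute at exactly the bulk concentration and are invisible
against the background; a small super-filled subpopulation (default 1%)
carries an internal/external concentration ratio r_F drawn from a
positively skewed distribution averaging 3-4.  Concentration maps to
8-bit pixel intensity through a linear calibration (no self-quenching),
vesicles are rendered as great-circle disks with Gaussian PSF blur,
shot noise and read noise, and frames plus per-vesicle ground truth are
written as TIFF + CSV + JSON so the analysis pipeline can be validated
end to end without any real micrograph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .geometry import SoluteSpec, sphere_volume
from .units import AVOGADRO, L_PER_FL

__all__ = [
    "PopulationConfig",
    "VesicleRecord",
    "CalibrationCurve",
    "FrameGeometry",
    "NoiseModel",
    "FrameSet",
    "sample_population",
    "apply_calibration",
    "render_frame",
    "render_kinetic_series",
    "dequench_scale",
    "write_fixture",
    "read_fixture",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a synthetic vesicle population.

    Diameters are drawn from a log-normal moment-matched to
    (diameter_mean, diameter_sd) and truncated to diameter_bounds.
    ``rf_distribution`` controls the super-filled concentration ratios:
    family "lognormal" (default, skewed like protein solutes) or
    "normal" (like the dextran case), truncated at 1.
    """

    n_vesicles: int
    solute: SoluteSpec
    diameter_mean: float = 1.3
    diameter_sd: float = 0.6
    diameter_bounds: tuple[float, float] = (0.4, 6.0)
    superfilled_fraction: float = 0.01
    rf_family: str = "lognormal"
    rf_mean: float = 3.5
    rf_sd: float = 1.5
    field_width: float = 102.4  # um, square field of view
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vesicles <= 0:
            raise ValueError("n_vesicles must be positive")
        if not 0.0 <= self.superfilled_fraction <= 1.0:
            raise ValueError("superfilled_fraction must be in [0, 1]")
        lo, hi = self.diameter_bounds
        if not lo < self.diameter_mean < hi:
            raise ValueError("diameter_mean must lie within diameter_bounds")
        if self.rf_family not in ("lognormal", "normal"):
            raise ValueError("rf_family must be 'lognormal' or 'normal'")


@dataclass(frozen=True)
class VesicleRecord:
    """Ground truth for one rendered vesicle."""

    id: int
    diameter: float  # um
    is_superfilled: bool
    occupancy: int
    lumen_concentration: float  # mol/L
    r_f_true: float
    center: tuple[float, float]  # (x, y) um


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear concentration -> 8-bit intensity calibration.

    ``intensity = slope * C + intercept`` clipped to [0, max_intensity];
    strictly increasing and invertible below saturation.
    """

    slope: float  # intensity units per mol/L
    intercept: float = 0.0
    max_intensity: int = 255

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    @classmethod
    def for_background(
        cls, bulk_concentration: float, background_level: float = 40.0, intercept: float = 0.0
    ) -> "CalibrationCurve":
        """Calibration placing the bulk solution at a target intensity.

        The zero default intercept makes the intensity ratio F/F0 equal
        the concentration ratio exactly, which is what r_F assumes; a
        non-zero instrumental offset can be supplied for sensitivity
        analysis (it biases r_F toward 1)."""
        if bulk_concentration <= 0:
            raise ValueError("bulk_concentration must be positive")
        return cls(slope=(background_level - intercept) / bulk_concentration, intercept=intercept)

    def intensity_float(self, concentration):
        """Unquantized, unclipped intensity (for rendering before noise)."""
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def invert(self, intensity):
        """Concentration from (unsaturated) intensity."""
        return (np.asarray(intensity, dtype=float) - self.intercept) / self.slope

    @property
    def saturation_concentration(self) -> float:
        return (self.max_intensity - self.intercept) / self.slope


class CalibratedIntensity(NamedTuple):
    intensity: np.ndarray | int
    saturated: bool


def apply_calibration(concentration, cal: CalibrationCurve) -> CalibratedIntensity:
    """Quantized 8-bit intensity for a concentration, with saturation flag."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    raw = cal.intensity_float(c)
    saturated = bool(np.any(raw > cal.max_intensity))
    quantized = np.clip(np.rint(raw), 0, cal.max_intensity).astype(np.uint8)
    if np.isscalar(concentration):
        return CalibratedIntensity(int(quantized), saturated)
    return CalibratedIntensity(quantized, saturated)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _truncated_draw(rng, draw_fn, lo, hi, size, max_rounds=200):
    out = np.empty(0)
    while len(out) < size:
        x = draw_fn(rng, size)
        out = np.concatenate([out, x[(x >= lo) & (x <= hi)]])
        max_rounds -= 1
        if max_rounds <= 0:
            raise RuntimeError("truncated sampling did not converge; check bounds")
    return out[:size]


def sample_population(config: PopulationConfig) -> list[VesicleRecord]:
    """Draw a seeded vesicle population with non-overlapping centres.

    A fraction ``superfilled_fraction`` of vesicles is flagged
    super-filled and assigned r_f_true > 1 from the configured
    distribution; all others sit at exactly the bulk concentration
    (r_f_true = 1, invisible against the background).  Centres are
    placed by dart throwing within the square field of view; a field
    too small for the requested count raises.
    """
    rng = np.random.default_rng(config.seed)
    mu_d, sig_d = _lognormal_params(config.diameter_mean, config.diameter_sd)
    lo, hi = config.diameter_bounds
    diameters = _truncated_draw(
        rng, lambda r, n: r.lognormal(mu_d, sig_d, n), lo, hi, config.n_vesicles
    )

    n_super = int(round(config.superfilled_fraction * config.n_vesicles))
    super_idx = rng.choice(config.n_vesicles, size=n_super, replace=False)
    r_f = np.ones(config.n_vesicles)
    if n_super:
        if config.rf_family == "lognormal":
            mu_r, sig_r = _lognormal_params(config.rf_mean, config.rf_sd)
            draw = lambda r, n: r.lognormal(mu_r, sig_r, n)
        else:
            draw = lambda r, n: r.normal(config.rf_mean, config.rf_sd, n)
        r_f[super_idx] = _truncated_draw(rng, draw, 1.0, np.inf, n_super)

    centers = _place_centers(rng, diameters, config.field_width)

    bulk = config.solute.bulk_concentration
    records = []
    for i in range(config.n_vesicles):
        lumen = r_f[i] * bulk
        occ = int(round(AVOGADRO * lumen * sphere_volume(diameters[i]) * L_PER_FL))
        records.append(
            VesicleRecord(
                id=i,
                diameter=float(diameters[i]),
                is_superfilled=bool(i in set(super_idx)),
                occupancy=occ,
                lumen_concentration=float(lumen),
                r_f_true=float(r_f[i]),
                center=(float(centers[i, 0]), float(centers[i, 1])),
            )
        )
    return records


def _place_centers(rng, diameters, field_width, max_attempts_per=200):
    """Dart-throwing placement with a uniform grid for neighbour lookup."""
    n = len(diameters)
    if np.sum(np.pi * (diameters / 2.0) ** 2) > 0.5 * field_width**2:
        raise ValueError(
            f"field of view {field_width} um too small for {n} vesicles; "
            "enlarge field_width or split the population across frames"
        )
    cell = max(float(np.max(diameters)), 1e-6)
    n_cells = max(1, int(field_width / cell))
    cell = field_width / n_cells
    grid: dict[tuple[int, int], list[int]] = {}
    order = np.argsort(diameters)[::-1]  # large first eases packing
    centers = np.empty((n, 2))
    radii = diameters / 2.0
    for idx in order:
        r = radii[idx]
        for _ in range(max_attempts_per):
            xy = rng.uniform(r, field_width - r, size=2)
            ci, cj = int(xy[0] / cell), int(xy[1] / cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for j in grid.get((ci + di, cj + dj), ()):
                        if np.hypot(*(xy - centers[j])) <= r + radii[j]:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                break
        else:
            raise ValueError("could not place all vesicles without overlap")
        centers[idx] = xy
        grid.setdefault((ci, cj), []).append(idx)
    return centers


@dataclass(frozen=True)
class FrameGeometry:
    """Raster geometry of one synthetic frame."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.2  # um per pixel
    psf_sigma: float = 0.2  # um, Gaussian PSF standard deviation


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise applied after blurring.

    ``poisson_scaling`` is the photon count corresponding to one
    intensity unit (shot noise SD = sqrt(I/poisson_scaling));
    ``gaussian_sd`` is additive read noise in intensity units.
    """

    gaussian_sd: float = 1.0
    poisson_scaling: float = 5.0


@dataclass
class FrameSet:
    """A stack of rendered frames with shared geometry and timestamps."""

    frames: list[np.ndarray]
    pixel_size: float
    timestamps: Sequence[float]
    optical_thickness: float = 0.9  # um confocal section
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")


def _paint_disks(image, records, lumen_intensities, geometry: FrameGeometry):
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for rec, inten in zip(records, lumen_intensities):
        cx, cy = rec.center
        r_px = rec.diameter / 2.0 / geometry.pixel_size
        cx_px, cy_px = cx / geometry.pixel_size, cy / geometry.pixel_size
        x0, x1 = max(0, int(cx_px - r_px - 2)), min(w, int(cx_px + r_px + 3))
        y0, y1 = max(0, int(cy_px - r_px - 2)), min(h, int(cy_px + r_px + 3))
        if x0 >= x1 or y0 >= y1:
            continue
        sub = (xx[y0:y1, x0:x1] - cx_px) ** 2 + (yy[y0:y1, x0:x1] - cy_px) ** 2 <= r_px**2
        patch = image[y0:y1, x0:x1]
        patch[sub] = inten


def render_frame(
    records: Sequence[VesicleRecord],
    bulk_concentration: float,
    cal: CalibrationCurve,
    geometry: FrameGeometry = FrameGeometry(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    lumen_intensities=None,
) -> np.ndarray:
    """Render one 8-bit frame: background + vesicle disks + PSF + noise.

    Every vesicle is drawn as a uniform disk of its great-circle
    diameter at its calibrated lumen intensity (r_f_true = 1 renders at
    exactly background, hence invisible).  ``lumen_intensities``
    overrides the per-vesicle intensity (used by the kinetic renderer).
    """
    rng = np.random.default_rng(seed)
    background = float(cal.intensity_float(bulk_concentration))
    image = np.full(geometry.shape, background, dtype=float)
    if lumen_intensities is None:
        lumen_intensities = [
            float(cal.intensity_float(rec.lumen_concentration)) for rec in records
        ]
    _paint_disks(image, records, lumen_intensities, geometry)
    image = gaussian_filter(image, sigma=geometry.psf_sigma / geometry.pixel_size)
    if noise.poisson_scaling > 0:
        image = rng.poisson(np.clip(image, 0, None) * noise.poisson_scaling) / noise.poisson_scaling
    if noise.gaussian_sd > 0:
        image = image + rng.normal(0.0, noise.gaussian_sd, size=image.shape)
    return np.clip(np.rint(image), 0, cal.max_intensity).astype(np.uint8)


def dequench_scale(digested_fraction, dequench_factor: float = 13.0):
    """Fluorescence multiplier for partially digested self-quenched label.

    Proteolysis of a FITC-labelled protein relieves self-quenching:
    complete digestion brightens the label ~13-fold.  Returns
    ``1 + (dequench_factor - 1) * digested_fraction``.
    """
    frac = np.asarray(digested_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("digested_fraction must be in [0, 1]")
    return 1.0 + (dequench_factor - 1.0) * frac


def render_kinetic_series(
    records: Sequence[VesicleRecord],
    traces: dict,
    bulk_trace,
    timestamps: Sequence[float],
    cal: CalibrationCurve,
    geometry: FrameGeometry = FrameGeometry(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> FrameSet:
    """Render frames at given times from per-vesicle kinetic traces.

    ``traces`` maps vesicle id -> KineticTrace; the lumen of each
    vesicle follows its trace's product_in(t) and the background follows
    ``bulk_trace``'s product_out(t).  At t = 0 (no product anywhere)
    vesicles are indistinguishable from the background.
    """
    t_max = float(bulk_trace.time[-1])
    for t in timestamps:
        if t < bulk_trace.time[0] or t > t_max:
            raise ValueError(f"timestamp {t} outside simulated trace")
    frames = []
    rng = np.random.default_rng(seed)
    for t in timestamps:
        bg_conc = float(np.interp(t, bulk_trace.time, bulk_trace.product_out))
        lumen = []
        for rec in records:
            tr = traces[rec.id]
            lumen.append(float(cal.intensity_float(np.interp(t, tr.time, tr.product_in))))
        frame = render_frame(
            records,
            bg_conc,
            cal,
            geometry=geometry,
            noise=noise,
            seed=int(rng.integers(2**31)),
            lumen_intensities=lumen,
        )
        frames.append(frame)
    return FrameSet(
        frames=frames, pixel_size=geometry.pixel_size, timestamps=list(timestamps), noise=noise
    )


def _records_frame(records: Sequence[VesicleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "x_um": [r.center[0] for r in records],
            "y_um": [r.center[1] for r in records],
            "diameter_um": [r.diameter for r in records],
            "r_f_true": [r.r_f_true for r in records],
            "is_superfilled": [r.is_superfilled for r in records],
            "occupancy": [r.occupancy for r in records],
            "lumen_concentration_M": [r.lumen_concentration for r in records],
        }
    )


def write_fixture(
    records: Sequence[VesicleRecord],
    frameset: FrameSet,
    path,
    config: dict | None = None,
) -> dict:
    """Write frames (TIFF per timestamp), ground truth CSV, config JSON.

    Returns the manifest of written file paths; a TIFF read back
    reproduces the rendered array bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tiff_paths = []
    for i, (frame, t) in enumerate(zip(frameset.frames, frameset.timestamps)):
        p = path / f"frame_t{i:03d}.tiff"
        tifffile.imwrite(p, frame)
        tiff_paths.append(str(p))
    truth_path = path / "ground_truth.csv"
    _records_frame(records).to_csv(truth_path, index=False)
    meta = {
        "pixel_size_um": frameset.pixel_size,
        "optical_thickness_um": frameset.optical_thickness,
        "timestamps_s": list(frameset.timestamps),
        "noise": asdict(frameset.noise),
        "frames": [Path(p).name for p in tiff_paths],
    }
    if config:
        meta["config"] = config
    config_path = path / "fixture.json"
    config_path.write_text(json.dumps(meta, indent=2))
    return {"frames": tiff_paths, "ground_truth": str(truth_path), "config": str(config_path)}


def read_fixture(path):
    """Read back a written fixture: (frames, ground-truth DataFrame, meta)."""
    path = Path(path)
    meta = json.loads((path / "fixture.json").read_text())
    frames = [tifffile.imread(path / name) for name in meta["frames"]]
    truth = pd.read_csv(path / "ground_truth.csv")
    return frames, truth, meta
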