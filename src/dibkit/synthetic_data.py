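"""Synthetic instrument-output generators.

Three generators emulate the raw data the analysis pipeline consumes:

* osmotically shrinking droplet pairs (trajectories and rendered frames),
* DSC endotherms on a linear instrument baseline,
* Raman spectra as sums of band profiles over a polynomial baseline.

Every generator records its ground truth in the returned object's metadata
and is bit-reproducible from its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from ._ode import (
    CONSTANT_CONTACT_ANGLE,
    CONSTANT_CONTACT_RADIUS,
    SHRINKAGE_MODES,
    integrate_pair_volumes,
)
from .droplet_geometry import (
    DropletPairState,
    ImageFrame,
    Trajectory,
    radius_from_volume,
    truncated_sphere_volume,
)
from .dsc import Thermogram
from .errors import ConfigError, GeometryError
from .raman import RamanSpectrum

__all__ = [
    "DIBSimConfig",
    "DSCSimConfig",
    "RamanSimConfig",
    "Band",
    "simulate_dib_trajectory",
    "render_droplet_image",
    "render_trajectory_frames",
    "simulate_thermogram",
    "simulate_raman_spectrum",
    "calibrate_ch_band_amplitudes",
    "mosm_per_kg_to_osmol_per_l",
    "DOPC_CH_BANDS",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


def mosm_per_kg_to_osmol_per_l(mosm_per_kg: float, density_kg_per_l: float = 1.0) -> float:
    """Convert measured osmolality (mOsm/kg solvent) to osmolarity (osmol/L)
    under an explicit dilute-solution density convention (default 1 kg/L)."""
    return mosm_per_kg * 1e-3 * density_kg_per_l


# ---------------------------------------------------------------------------
# droplet-pair trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DIBSimConfig:
    """Ground-truth configuration for a droplet-pair shrinkage simulation.

    Radii and contact radius in μm, osmolarities in osmol/L, permeability in
    μm/s, water molar volume in cm³/mol, times in seconds.
    """

    initial_radius_1: float = 50.0
    initial_radius_2: float = 50.0
    initial_contact_radius: float = 30.0
    osmolality_1: float = 0.0
    osmolality_2: float = 0.2
    true_Pf: float = 74.0
    v_w: float = 18.0
    duration: float = 60.0
    sample_interval: float = 1.0
    shrinkage_mode: str = CONSTANT_CONTACT_RADIUS
    noise_sd_radius: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (self.initial_radius_1 > 0 and self.initial_radius_2 > 0):
            raise ConfigError("initial radii must be positive")
        if not (
            0 <= self.initial_contact_radius
            < min(self.initial_radius_1, self.initial_radius_2)
        ):
            raise ConfigError("contact radius must satisfy 0 <= rc < min(R1, R2)")
        if self.osmolality_1 < 0 or self.osmolality_2 < 0:
            raise ConfigError("osmolarities must be non-negative")
        if self.true_Pf < 0:
            raise ConfigError("true_Pf must be non-negative")
        if self.v_w <= 0:
            raise ConfigError("v_w must be positive")
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ConfigError("duration and sample_interval must be positive")
        if self.shrinkage_mode not in SHRINKAGE_MODES:
            raise ConfigError(f"shrinkage_mode must be one of {SHRINKAGE_MODES}")
        if self.noise_sd_radius < 0:
            raise ConfigError("noise_sd_radius must be non-negative")


def simulate_dib_trajectory(config: DIBSimConfig) -> Trajectory:
    """Forward-simulate osmotic shrinkage of an adhered droplet pair.

    Water crosses the bilayer toward the hyperosmotic droplet; solute
    amounts per droplet are conserved. Gaussian measurement noise (if any)
    is added to the sphere radii after integration.
    """
    c = config
    t = np.arange(0.0, c.duration + c.sample_interval / 2, c.sample_interval)
    V1_0 = truncated_sphere_volume(c.initial_radius_1, c.initial_contact_radius)
    V2_0 = truncated_sphere_volume(c.initial_radius_2, c.initial_contact_radius)
    V1, V2, rc = integrate_pair_volumes(
        V1_0,
        V2_0,
        c.initial_contact_radius,
        c.osmolality_1,
        c.osmolality_2,
        c.true_Pf,
        c.v_w,
        t,
        shrinkage_mode=c.shrinkage_mode,
    )
    R1 = np.array([radius_from_volume(v, r) for v, r in zip(V1, rc)])
    R2 = np.array([radius_from_volume(v, r) for v, r in zip(V2, rc)])
    if c.noise_sd_radius > 0:
        rng = np.random.default_rng(c.seed)
        R1 = R1 + rng.normal(0.0, c.noise_sd_radius, size=R1.shape)
        R2 = R2 + rng.normal(0.0, c.noise_sd_radius, size=R2.shape)
    meta = {
        "true_Pf": c.true_Pf,
        "osmolality_1": c.osmolality_1,
        "osmolality_2": c.osmolality_2,
        "v_w": c.v_w,
        "shrinkage_mode": c.shrinkage_mode,
        "noise_sd_radius": c.noise_sd_radius,
        "seed": c.seed,
        "V1_um3": V1,
        "V2_um3": V2,
    }
    return Trajectory(t, R1, R2, rc, meta=meta)


def render_droplet_image(
    state: DropletPairState,
    pixel_size: float,
    image_shape: tuple[int, int] = (256, 256),
    timestamp: float = 0.0,
) -> ImageFrame:
    """Render a droplet pair as two overlapping bright disks on a dark
    background with a one-pixel anti-aliased edge ramp.

    The half-maximum iso-contour of each disk lies exactly at its radius, so
    geometry round-trips through :func:`droplet_geometry.fit_droplet_pair`.
    Ground truth is recorded in ``frame.truth``.
    """
    if pixel_size <= 0:
        raise GeometryError("pixel_size must be positive")
    h, w = image_shape
    d_px = state.center_distance / pixel_size
    r1_px = state.R1 / pixel_size
    r2_px = state.R2 / pixel_size
    cy = (h - 1) / 2.0
    cx_mid = (w - 1) / 2.0
    cx1 = cx_mid - d_px / 2.0
    cx2 = cx_mid + d_px / 2.0
    if (
        cx1 - r1_px < 1
        or cx2 + r2_px > w - 2
        or cy - max(r1_px, r2_px) < 1
        or cy + max(r1_px, r2_px) > h - 2
    ):
        raise GeometryError(
            f"droplets (radii {r1_px:.1f}, {r2_px:.1f} px, separation {d_px:.1f} px) "
            f"do not fit in a {h}x{w} frame"
        )
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d1 = np.hypot(xx - cx1, yy - cy)
    d2 = np.hypot(xx - cx2, yy - cy)
    disk1 = np.clip(r1_px + 0.5 - d1, 0.0, 1.0)
    disk2 = np.clip(r2_px + 0.5 - d2, 0.0, 1.0)
    img = np.maximum(disk1, disk2)
    truth = {
        "R1_um": state.R1,
        "R2_um": state.R2,
        "rc_um": state.rc,
        "d_um": state.center_distance,
        "centers_px": [[cx1, cy], [cx2, cy]],
        "pixel_size_um": pixel_size,
    }
    return ImageFrame(img, pixel_size, timestamp=timestamp, truth=truth)


def render_trajectory_frames(
    traj: Trajectory, pixel_size: float, image_shape: tuple[int, int] = (256, 256)
) -> list[ImageFrame]:
    """Render each trajectory sample as an image frame (timestamps carried)."""
    return [
        render_droplet_image(
            traj.state(i), pixel_size, image_shape, timestamp=traj.time_s[i]
        )
        for i in range(len(traj))
    ]


# ---------------------------------------------------------------------------
# DSC thermograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSCSimConfig:
    """Ground truth for a synthetic endotherm (heating scan, endotherm-up)."""

    Tm_true: float = -17.08  # °C
    dH_true: float = 8.76  # kcal/mol
    dT_half_true: float = 2.04  # °C (FWHM)
    peak_shape: Literal["gaussian", "skewed_gaussian"] = "gaussian"
    skew: float = 0.0
    baseline_slope: float = 0.0  # mW per °C
    baseline_intercept: float = 0.0  # mW
    scan_rate: float = 5.0  # °C/min
    sample_moles: float = 3.05e-7  # mol
    T_range: tuple[float, float] = (-40.0, 0.0)
    T_step: float = 0.02  # °C
    noise_sd: float = 0.0  # mW
    seed: int | None = None

    def __post_init__(self):
        if self.dH_true <= 0:
            raise ConfigError("dH_true must be positive")
        if self.dT_half_true <= 0:
            raise ConfigError("dT_half_true must be positive")
        lo, hi = self.T_range
        if not (lo < self.Tm_true < hi):
            raise ConfigError("Tm_true must lie inside T_range")
        if self.scan_rate <= 0:
            raise ConfigError("scan_rate must be positive")
        if self.sample_moles <= 0:
            raise ConfigError("sample_moles must be positive")
        if self.T_step <= 0 or self.noise_sd < 0:
            raise ConfigError("T_step must be positive and noise_sd non-negative")
        if self.peak_shape not in ("gaussian", "skewed_gaussian"):
            raise ConfigError("peak_shape must be gaussian or skewed_gaussian")


def _skewnorm_mode_fwhm(alpha: float) -> tuple[float, float]:
    """Mode and FWHM of the standard skew-normal pdf (loc 0, scale 1)."""
    grid = np.linspace(-6, 6, 4001)
    pdf = stats.skewnorm.pdf(grid, alpha)
    i = int(np.argmax(pdf))
    mode = float(
        optimize.minimize_scalar(
            lambda x: -stats.skewnorm.pdf(x, alpha),
            bracket=(grid[max(i - 1, 0)], grid[i], grid[min(i + 1, len(grid) - 1)]),
        ).x
    )
    pmax = stats.skewnorm.pdf(mode, alpha)
    half = pmax / 2.0
    f = lambda x: stats.skewnorm.pdf(x, alpha) - half
    left = optimize.brentq(f, -8.0, mode, xtol=1e-12)
    right = optimize.brentq(f, mode, 8.0, xtol=1e-12)
    return mode, right - left


def excess_cp_profile(T: np.ndarray, config: DSCSimConfig) -> np.ndarray:
    """Ground-truth molar excess heat capacity (kcal·mol⁻¹·°C⁻¹) at ``T``.

    The profile integrates to ``dH_true``, peaks at ``Tm_true`` and has full
    width at half maximum ``dT_half_true`` for either shape.
    """
    T = np.asarray(T, dtype=float)
    if config.peak_shape == "gaussian" or config.skew == 0.0:
        sigma = config.dT_half_true / GAUSSIAN_FWHM_FACTOR
        return config.dH_true * stats.norm.pdf(T, loc=config.Tm_true, scale=sigma)
    mode0, fwhm0 = _skewnorm_mode_fwhm(config.skew)
    omega = config.dT_half_true / fwhm0
    xi = config.Tm_true - omega * mode0
    return config.dH_true * stats.skewnorm.pdf(T, config.skew, loc=xi, scale=omega)


def simulate_thermogram(config: DSCSimConfig) -> Thermogram:
    """Generate an endotherm-up heat-flow trace (mW) on a uniform grid.

    heat flow = Cp_excess · 4184 J/kcal · moles · scan rate (°C/s) · 1000,
    plus a linear instrument baseline and optional Gaussian noise.
    Sets ``meta['truncated']`` (with a warning) when the apex or either
    half-height point falls outside ``T_range``.
    """
    c = config
    lo, hi = c.T_range
    T = np.arange(lo, hi + c.T_step / 2, c.T_step)
    cp = excess_cp_profile(T, c)
    scan_rate_C_per_s = c.scan_rate / 60.0
    heatflow = cp * 4184.0 * c.sample_moles * scan_rate_C_per_s * 1000.0
    heatflow = heatflow + c.baseline_slope * T + c.baseline_intercept
    if c.noise_sd > 0:
        rng = np.random.default_rng(c.seed)
        heatflow = heatflow + rng.normal(0.0, c.noise_sd, size=T.shape)

    truncated = (
        c.Tm_true - c.dT_half_true < lo + c.T_step
        or c.Tm_true + c.dT_half_true > hi - c.T_step
    )
    if truncated:
        warnings.warn(
            "endotherm peak is truncated by the temperature range", stacklevel=2
        )
    meta = {
        "Tm_true": c.Tm_true,
        "dH_true": c.dH_true,
        "dT_half_true": c.dT_half_true,
        "peak_shape": c.peak_shape,
        "baseline_slope": c.baseline_slope,
        "baseline_intercept": c.baseline_intercept,
        "noise_sd": c.noise_sd,
        "seed": c.seed,
        "truncated": truncated,
    }
    return Thermogram(T, heatflow, c.scan_rate, c.sample_moles, meta=meta)


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One spectral band: centre and FWHM in cm⁻¹, peak height in intensity
    units, profile shape."""

    center: float
    width: float
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def profile(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(
                -4.0 * np.log(2.0) * ((x - self.center) / self.width) ** 2
            )
        if self.shape == "lorentzian":
            return self.amplitude / (1.0 + (2.0 * (x - self.center) / self.width) ** 2)
        raise ConfigError(f"unknown band shape {self.shape!r}")


# band centres characteristic of a DOPC bilayer plus the isoflavone marker
DOPC_CH_BANDS = (1300.0, 1440.0, 1614.0, 1650.0, 2848.0, 2890.0, 2930.0)


@dataclass(frozen=True)
class RamanSimConfig:
    """Ground truth for a synthetic Raman spectrum."""

    band_table: tuple[Band, ...] = ()
    baseline_poly_coeffs: tuple[float, ...] = ()  # increasing powers of x
    noise_sd: float = 0.0
    wavenumber_range: tuple[float, float] = (2700.0, 3100.0)
    step: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        bands = tuple(
            b if isinstance(b, Band) else Band(*b) for b in self.band_table
        )
        object.__setattr__(self, "band_table", bands)
        lo, hi = self.wavenumber_range
        if self.step <= 0:
            raise ConfigError("step must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for b in bands:
            if not (lo <= b.center <= hi):
                raise ConfigError(f"band centre {b.center} outside wavenumber range")
            if b.width <= 0:
                raise ConfigError("band widths must be positive")
            if b.amplitude < 0:
                raise ConfigError("band amplitudes must be non-negative")


def simulate_raman_spectrum(config: RamanSimConfig) -> RamanSpectrum:
    """Sum of band profiles plus polynomial baseline plus Gaussian noise."""
    c = config
    lo, hi = c.wavenumber_range
    x = np.arange(lo, hi + c.step / 2, c.step)
    y = np.zeros_like(x)
    for band in c.band_table:
        y += band.profile(x)
    if c.baseline_poly_coeffs:
        y += np.polynomial.polynomial.polyval(x, np.asarray(c.baseline_poly_coeffs))
    if c.noise_sd > 0:
        rng = np.random.default_rng(c.seed)
        y = y + rng.normal(0.0, c.noise_sd, size=x.shape)
    meta = {
        "bands": [
            {
                "center": b.center,
                "width": b.width,
                "amplitude": b.amplitude,
                "shape": b.shape,
            }
            for b in c.band_table
        ],
        "baseline_poly_coeffs": list(c.baseline_poly_coeffs),
        "noise_sd": c.noise_sd,
        "seed": c.seed,
    }
    return RamanSpectrum(x, y, meta=meta)


def calibrate_ch_band_amplitudes(
    ratio_2930_2848: float,
    ratio_2930_2890: float,
    centers: tuple[float, float, float] = (2848.0, 2890.0, 2930.0),
    width: float = 15.0,
    shape: str = "gaussian",
) -> tuple[Band, Band, Band]:
    """Tune the three C–H band amplitudes so the *composite* spectrum's
    measured peak heights yield the target intensity ratios.

    Overlapping band tails make composite peak heights differ from the
    individual amplitudes, so the amplitudes are solved numerically such
    that the measured heights are (1, r1/r2, r1) at (2848, 2890, 2930),
    giving I2930/I2848 = r1 and I2930/I2890 = r2 exactly.
    """
    from .raman import band_intensity

    r1, r2 = ratio_2930_2848, ratio_2930_2890
    targets = np.array([1.0, r1 / r2, r1])
    x = np.arange(centers[0] - 100.0, centers[2] + 100.0, 0.1)

    def measured_heights(amps: np.ndarray) -> np.ndarray:
        y = np.zeros_like(x)
        for c0, a in zip(centers, amps):
            y += Band(c0, width, float(a), shape).profile(x)
        spec = RamanSpectrum(x, y)
        return np.array(
            [band_intensity(spec, c0, window=10.0).intensity for c0 in centers]
        )

    sol = optimize.least_squares(
        lambda a: measured_heights(a) - targets,
        x0=targets.copy(),
        bounds=(0.0, np.inf),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    amps = sol.x
    if np.max(np.abs(measured_heights(amps) - targets)) > 1e-6:
        raise ConfigError("band amplitude calibration did not converge")
    return tuple(
        Band(c0, width, float(a), shape) for c0, a in zip(centers, amps)
    )
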