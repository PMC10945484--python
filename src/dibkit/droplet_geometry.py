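"""Droplet-pair geometry: truncated-sphere volumes, bilayer contact area, and
image-based extraction of the pair state.

Two adhered aqueous microdroplets in oil each take the shape of a sphere
truncated by the planar bilayer disc at their mutual contact. All lengths are
micrometres unless a ``pixel_size`` converts from pixels.

Image coordinate convention: origin at the top-left pixel centre, ``x`` is the
column index, ``y`` the row index, pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .errors import DetectionError, GeometryError, TrackingError

__all__ = [
    "DropletPairState",
    "ImageFrame",
    "Trajectory",
    "truncated_sphere_volume",
    "contact_area",
    "contact_radius_from_centers",
    "center_distance_from_contact",
    "radius_from_volume",
    "fit_droplet_pair",
    "track_trajectory",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletPairState:
    """Instantaneous geometry of two adhered droplets.

    Parameters
    ----------
    R1, R2 : float
        Sphere radii in μm.
    rc : float
        Contact (bilayer) radius in μm, ``0 <= rc < min(R1, R2)``.
    d : float, optional
        Centre-to-centre distance in μm. If omitted it is derived from the
        radii and the contact radius.
    """

    R1: float
    R2: float
    rc: float
    d: float | None = None
    fit_residuals: tuple[float, float] | None = None

    def __post_init__(self):
        if not (self.R1 > 0 and self.R2 > 0):
            raise GeometryError(f"radii must be positive, got {self.R1}, {self.R2}")
        if not (0 <= self.rc < min(self.R1, self.R2)):
            raise GeometryError(
                f"contact radius {self.rc} must satisfy 0 <= rc < min(R1, R2)"
            )
        if self.d is not None and self.rc > 0:
            if not (abs(self.R1 - self.R2) < self.d < self.R1 + self.R2):
                raise GeometryError(
                    f"centre distance {self.d} inconsistent with intersecting "
                    f"spheres of radii {self.R1}, {self.R2}"
                )

    @property
    def center_distance(self) -> float:
        """Centre distance, derived from (R1, R2, rc) when not stored."""
        if self.d is not None:
            return self.d
        return center_distance_from_contact(self.R1, self.R2, self.rc)

    def volumes(self) -> tuple[float, float]:
        """Truncated-sphere volumes (V1, V2) in μm³."""
        return (
            truncated_sphere_volume(self.R1, self.rc),
            truncated_sphere_volume(self.R2, self.rc),
        )


@dataclass(frozen=True)
class ImageFrame:
    """A single intensity image with physical pixel size and timestamp."""

    intensity: np.ndarray
    pixel_size: float  # μm per pixel
    timestamp: float = 0.0  # s
    truth: dict | None = None  # generator ground truth, if synthetic

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("intensity must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "intensity", arr)


@dataclass
class Trajectory:
    """Time series of droplet-pair geometry.

    Columns mirror the on-disk CSV schema: ``time_s, R1_um, R2_um, rc_um``.
    """

    time_s: np.ndarray
    R1_um: np.ndarray
    R2_um: np.ndarray
    rc_um: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.R1_um = np.asarray(self.R1_um, dtype=float)
        self.R2_um = np.asarray(self.R2_um, dtype=float)
        self.rc_um = np.asarray(self.rc_um, dtype=float)
        n = len(self.time_s)
        if not (len(self.R1_um) == len(self.R2_um) == len(self.rc_um) == n):
            raise ValueError("trajectory arrays must have equal length")

    def __len__(self) -> int:
        return len(self.time_s)

    def state(self, i: int) -> DropletPairState:
        return DropletPairState(self.R1_um[i], self.R2_um[i], self.rc_um[i])

    def volumes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample truncated-sphere volumes (V1, V2) in μm³."""
        v1 = truncated_sphere_volume(self.R1_um, self.rc_um)
        v2 = truncated_sphere_volume(self.R2_um, self.rc_um)
        return v1, v2


# ---------------------------------------------------------------------------
# closed-form geometry
# ---------------------------------------------------------------------------


def truncated_sphere_volume(R, rc):
    """Volume (μm³) of a sphere of radius ``R`` truncated by the bilayer plane.

    The spherical cap beyond the contact disc of radius ``rc`` is removed;
    cap height ``h = R - sqrt(R² - rc²)``. Accepts scalars or arrays.
    """
    R = np.asarray(R, dtype=float)
    rc = np.asarray(rc, dtype=float)
    if np.any(rc < 0) or np.any(rc > R):
        raise GeometryError("require 0 <= rc <= R")
    h = R - np.sqrt(R * R - rc * rc)
    vol = 4.0 / 3.0 * np.pi * R**3 - np.pi * h * h * (3.0 * R - h) / 3.0
    return vol if vol.ndim else float(vol)


def contact_area(rc) -> float:
    """Bilayer disc area π·rc² (μm²)."""
    rc = np.asarray(rc, dtype=float)
    if np.any(rc < 0):
        raise GeometryError("contact radius must be non-negative")
    a = np.pi * rc * rc
    return a if a.ndim else float(a)


def contact_radius_from_centers(R1: float, R2: float, d: float) -> float:
    """Contact radius of two intersecting spheres from their centre distance.

    ``rc = sqrt(R1² - x²)`` with ``x = (d² + R1² - R2²) / (2d)``, the distance
    from centre 1 to the plane of intersection.
    """
    if d <= 0:
        raise GeometryError("centre distance must be positive")
    if d >= R1 + R2:
        if np.isclose(d, R1 + R2):
            return 0.0
        raise GeometryError(f"spheres do not intersect (d={d} >= R1+R2={R1 + R2})")
    if d <= abs(R1 - R2):
        raise GeometryError("one sphere contains the other (d <= |R1-R2|)")
    x = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    rc_sq = R1 * R1 - x * x
    if rc_sq < 0:
        raise GeometryError("inconsistent sphere intersection")
    return float(np.sqrt(rc_sq))


def center_distance_from_contact(R1: float, R2: float, rc: float) -> float:
    """Centre distance of two adhered spheres given the shared contact radius.

    Assumes the bilayer plane lies between the two centres (valid whenever
    ``rc < min(R1, R2)``, i.e. neither droplet is cut past its equator).
    """
    if not (0 <= rc < min(R1, R2)):
        raise GeometryError("require 0 <= rc < min(R1, R2)")
    return float(np.sqrt(R1 * R1 - rc * rc) + np.sqrt(R2 * R2 - rc * rc))


def radius_from_volume(V: float, rc: float) -> float:
    """Invert :func:`truncated_sphere_volume`: sphere radius for a given
    truncated volume at fixed contact radius.

    Requires ``V >= (2/3)π·rc³`` (the hemisphere limit ``R = rc``).
    """
    if rc < 0:
        raise GeometryError("contact radius must be non-negative")
    if rc == 0:
        return float((3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0))
    v_min = 2.0 / 3.0 * np.pi * rc**3
    if V < v_min * (1 - 1e-12):
        raise GeometryError(
            f"volume {V} below hemisphere limit {v_min} for rc={rc}"
        )
    # upper bracket: hemisphere of volume V has radius >= the solution
    r_hi = (3.0 * V / (2.0 * np.pi)) ** (1.0 / 3.0)
    if V <= v_min:
        return float(rc)

    # Newton with the analytic dV/dR, started from the full-sphere radius;
    # falls back to bisection bracketing on any misstep
    R = max((3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0), rc * (1.0 + 1e-9))
    for _ in range(100):
        s = np.sqrt(R * R - rc * rc)
        h = R - s
        f = 4.0 / 3.0 * np.pi * R**3 - np.pi * h * h * (3.0 * R - h) / 3.0 - V
        if s <= 1e-12 * R:
            break
        dh = 1.0 - R / s
        dV = 4.0 * np.pi * R * R - np.pi / 3.0 * (
            2.0 * h * dh * (3.0 * R - h) + h * h * (3.0 - dh)
        )
        if dV <= 0:
            break
        R_new = R - f / dV
        if not (rc < R_new <= r_hi * 1.01):
            break
        if abs(R_new - R) <= 1e-13 * R:
            return float(R_new)
        R = R_new
    return float(
        optimize.brentq(
            lambda r: truncated_sphere_volume(r, rc) - V, rc, r_hi, xtol=1e-12, rtol=1e-14
        )
    )


# ---------------------------------------------------------------------------
# image analysis
# ---------------------------------------------------------------------------


def _detect_initial_circles(binary: np.ndarray) -> list[tuple[float, float, float]]:
    """Initial (cx, cy, r) guesses in px from distance-transform maxima.

    For a union of two bright disks the Euclidean distance transform peaks at
    each disk centre with peak value equal to that disk's radius.
    """
    from scipy import ndimage
    from skimage.feature import peak_local_max

    dist = ndimage.distance_transform_edt(binary)
    rmax = float(dist.max())
    if rmax < 2.0:
        raise DetectionError(0, "no droplet-scale bright region found")
    peaks = peak_local_max(
        dist, min_distance=max(3, int(rmax * 0.5)), threshold_abs=0.4 * rmax
    )
    circles = [(float(c), float(r), float(dist[r, c])) for r, c in peaks]
    circles.sort(key=lambda t: -t[2])
    return circles


def _refine_circle(points: np.ndarray, cx: float, cy: float, r: float):
    """Geometric least-squares circle fit from an initial guess.

    ``points`` is (N, 2) array of (x, y) edge coordinates. Returns
    (cx, cy, r, rms_residual).
    """

    def residuals(p):
        return np.hypot(points[:, 0] - p[0], points[:, 1] - p[1]) - p[2]

    sol = optimize.least_squares(residuals, x0=[cx, cy, r], method="lm")
    res = residuals(sol.x)
    rms = float(np.sqrt(np.mean(res**2)))
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2]), rms


def fit_droplet_pair(frame: ImageFrame) -> DropletPairState:
    """Fit two overlapping droplets in an image frame.

    Pipeline: Otsu threshold → distance-transform peaks (one per droplet) →
    subpixel boundary from the half-maximum iso-contour → per-droplet
    geometric least-squares circle fit, excluding boundary points inside the
    sibling droplet (the contact chord region). The contact radius follows
    from the fitted centres and radii.

    Raises
    ------
    DetectionError
        If the number of droplet candidates differs from two.
    """
    from skimage import filters, measure

    img = frame.intensity
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise DetectionError(0, "blank frame")
    thresh = filters.threshold_otsu(img)
    binary = img > thresh
    if not binary.any():
        raise DetectionError(0, "no foreground after thresholding")

    circles = _detect_initial_circles(binary)
    if len(circles) != 2:
        raise DetectionError(len(circles))

    # subpixel union boundary at the half-max level (matches the renderer's
    # linear anti-aliased edge profile)
    level = lo + 0.5 * (hi - lo)
    contours = measure.find_contours(img, level)
    if not contours:
        raise DetectionError(0, "no iso-contour at half maximum")
    pts_rc = np.vstack(contours)  # (row, col)
    pts = pts_rc[:, ::-1].copy()  # (x, y)

    fitted = []
    for i, (cx, cy, r0) in enumerate(circles):
        ox, oy, orr = circles[1 - i]
        d_self = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        d_other = np.hypot(pts[:, 0] - ox, pts[:, 1] - oy)
        # points on this droplet's free arc: near its circle, outside sibling
        sel = (np.abs(d_self - r0) < max(2.0, 0.05 * r0)) & (d_other > orr - 0.5)
        if sel.sum() < 8:
            raise DetectionError(len(circles), "too few edge points per droplet")
        fitted.append(_refine_circle(pts[sel], cx, cy, r0))

    (c1x, c1y, r1, res1), (c2x, c2y, r2, res2) = fitted
    d_px = float(np.hypot(c1x - c2x, c1y - c2y))
    if d_px >= r1 + r2:
        rc_px = 0.0
    else:
        rc_px = contact_radius_from_centers(r1, r2, d_px)

    px = frame.pixel_size
    return DropletPairState(
        R1=r1 * px,
        R2=r2 * px,
        rc=rc_px * px,
        d=d_px * px if rc_px > 0 else None,
        fit_residuals=(res1 * px, res2 * px),
    )


def _fit_with_centers(frame: ImageFrame):
    """fit_droplet_pair plus raw pixel centres, for cross-frame tracking."""
    from skimage import filters

    img = frame.intensity
    thresh = filters.threshold_otsu(img)
    circles = _detect_initial_circles(img > thresh)
    if len(circles) != 2:
        raise DetectionError(len(circles))
    state = fit_droplet_pair(frame)
    centers = np.array([(c[0], c[1]) for c in circles])
    return state, centers


def track_trajectory(frames: Sequence[ImageFrame]) -> Trajectory:
    """Extract a trajectory from a sequence of frames, preserving droplet
    identity by nearest-centre matching between consecutive frames."""
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.array([f.timestamp for f in frames], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    R1s, R2s, rcs = [], [], []
    prev_centers = None
    order = (0, 1)
    for f in frames:
        state, centers = _fit_with_centers(f)
        radii = (state.R1, state.R2)
        if prev_centers is not None:
            d_same = np.linalg.norm(centers - prev_centers, axis=1).sum()
            d_swap = np.linalg.norm(centers[::-1] - prev_centers, axis=1).sum()
            if d_swap < d_same:
                centers = centers[::-1]
                radii = radii[::-1]
                order = (order[1], order[0])
            movement = np.linalg.norm(centers - prev_centers, axis=1)
            sep = np.linalg.norm(centers[0] - centers[1])
            if movement.sum() > sep:
                raise TrackingError(
                    "droplet centres moved more than their separation between "
                    "frames; identity assignment is ambiguous"
                )
        prev_centers = centers
        R1s.append(radii[0])
        R2s.append(radii[1])
        rcs.append(state.rc)

    return Trajectory(times, np.array(R1s), np.array(R2s), np.array(rcs))
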