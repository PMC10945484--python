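"""DSC endotherm analysis: calibration to molar excess heat capacity,
linear two-window baseline subtraction, and transition metrics
(T_m, ΔH, ΔT_1/2) with condition-vs-control comparisons.

Convention: heating scans, endotherm-up heat flow in mW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import AmbiguousPeakError, BaselineError, NoTransitionError

__all__ = [
    "Thermogram",
    "CpTrace",
    "TransitionMetrics",
    "ControlComparison",
    "heatflow_to_molar_cp",
    "subtract_baseline",
    "transition_metrics",
    "compare_to_control",
]

J_PER_KCAL = 4184.0


@dataclass
class Thermogram:
    """Temperature-resolved heat flow from a single heating scan."""

    temperature_C: np.ndarray
    heatflow_mW: np.ndarray
    scan_rate: float  # °C/min
    sample_moles: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.heatflow_mW = np.asarray(self.heatflow_mW, dtype=float)
        if self.temperature_C.shape != self.heatflow_mW.shape:
            raise ValueError("temperature and heat-flow arrays must match")
        dT = np.diff(self.temperature_C)
        if not (np.all(dT > 0) or np.all(dT < 0)):
            raise ValueError("temperature grid must be strictly monotone")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        if self.sample_moles <= 0:
            raise ValueError("sample_moles must be positive")


@dataclass
class CpTrace:
    """Molar (excess) heat capacity vs temperature, kcal·mol⁻¹·°C⁻¹."""

    temperature_C: np.ndarray
    cp: np.ndarray
    baseline: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature_C.shape != self.cp.shape:
            raise ValueError("temperature and cp arrays must match")


@dataclass(frozen=True)
class TransitionMetrics:
    Tm: float  # °C, apex
    dH: float  # kcal/mol, integrated area
    dT_half: float  # °C, width at half height
    baseline: dict | None = None

    def __post_init__(self):
        if self.dH < 0:
            raise ValueError("dH must be non-negative")
        if not self.dT_half > 0:
            raise ValueError("dT_half must be positive")


@dataclass(frozen=True)
class ControlComparison:
    dTm: float  # °C, Tm − Tm(control)
    dH_ratio: float  # ΔH / ΔH(control)

    def __post_init__(self):
        if self.dH_ratio < 0:
            raise ValueError("dH_ratio must be non-negative")


def heatflow_to_molar_cp(thermogram: Thermogram) -> CpTrace:
    """Convert instrument heat flow (mW) to molar heat capacity.

    Cp(T) = heat_flow / scan rate (°C/s) / moles / 4184, in
    kcal·mol⁻¹·°C⁻¹. Any instrument baseline passes through unchanged.
    """
    rate_C_per_s = thermogram.scan_rate / 60.0
    cp = (
        thermogram.heatflow_mW
        * 1e-3
        / rate_C_per_s
        / thermogram.sample_moles
        / J_PER_KCAL
    )
    return CpTrace(thermogram.temperature_C.copy(), cp)


def _window_mask(T: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = sorted(window)
    return (T >= lo) & (T <= hi)


def subtract_baseline(
    trace: CpTrace,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
) -> CpTrace:
    """Subtract the straight line through the mean points of two peak-free
    flanking windows.

    Raises
    ------
    BaselineError
        If either window is empty, or overlaps the transition peak (apex
        inside a window, or window residual exceeding 10% of peak height).
    """
    T, cp = trace.temperature_C, trace.cp
    m_pre = _window_mask(T, pre_window)
    m_post = _window_mask(T, post_window)
    if not m_pre.any() or not m_post.any():
        raise BaselineError("baseline window lies outside the temperature grid")
    t1, y1 = T[m_pre].mean(), cp[m_pre].mean()
    t2, y2 = T[m_post].mean(), cp[m_post].mean()
    if t1 == t2:
        raise BaselineError("baseline windows coincide")
    slope = (y2 - y1) / (t2 - t1)
    intercept = y1 - slope * t1
    excess = cp - (slope * T + intercept)

    apex_i = int(np.argmax(excess))
    peak_h = excess[apex_i]
    if peak_h > 0:
        if m_pre[apex_i] or m_post[apex_i]:
            raise BaselineError("baseline window contains the transition apex")
        for mask, name in ((m_pre, "pre"), (m_post, "post")):
            if np.max(np.abs(excess[mask])) > 0.10 * peak_h:
                raise BaselineError(
                    f"{name}-transition window overlaps the peak "
                    "(residual exceeds 10% of peak height)"
                )
    return CpTrace(
        T.copy(), excess, baseline={"slope": slope, "intercept": intercept}
    )


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic refinement of a grid maximum; returns (x*, y*)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    step = x[i + 1] - x[i]
    return float(x[i] + delta * step), float(y1 - 0.25 * (y0 - y2) * delta)


def _half_height_crossings(
    T: np.ndarray, y: np.ndarray, apex_i: int, half: float
) -> tuple[float, float]:
    left = None
    for j in range(apex_i, 0, -1):
        if y[j - 1] <= half <= y[j]:
            frac = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = T[j - 1] + frac * (T[j] - T[j - 1])
            break
    right = None
    for j in range(apex_i, len(y) - 1):
        if y[j + 1] <= half <= y[j]:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = T[j] + frac * (T[j + 1] - T[j])
            break
    if left is None or right is None:
        raise NoTransitionError("half-height crossings fall outside the grid")
    return float(left), float(right)


def transition_metrics(
    trace: CpTrace,
    peak_support_fraction: float = 0.01,
    noise_snr_threshold: float = 5.0,
    ambiguity_fraction: float = 0.5,
) -> TransitionMetrics:
    """Apex temperature, transition enthalpy and width at half height of the
    dominant endotherm in a baseline-subtracted excess-Cp trace.

    * T_m: parabolic-interpolated apex.
    * ΔH: trapezoidal integral over the contiguous support where the excess
      capacity exceeds ``peak_support_fraction`` of the maximum.
    * ΔT_1/2: linear-interpolated half-maximum crossing distance.

    Raises ``NoTransitionError`` when the maximum does not exceed
    ``noise_snr_threshold`` times the flanking noise SD, and
    ``AmbiguousPeakError`` when several peaks are comparable in height.
    """
    T, y = trace.temperature_C, trace.cp
    if T[0] > T[-1]:
        T, y = T[::-1], y[::-1]
    n = len(T)
    if n < 5:
        raise NoTransitionError("trace too short")

    apex_i = int(np.argmax(y))
    peak_h = float(y[apex_i])
    k = max(3, n // 10)
    flank = np.concatenate([y[:k], y[-k:]])
    noise_sd = float(np.std(flank))
    if peak_h <= 0 or (noise_sd > 0 and peak_h < noise_snr_threshold * noise_sd):
        raise NoTransitionError(
            f"no transition: peak {peak_h:.4g} vs flanking noise SD {noise_sd:.4g}"
        )

    # multiple comparable peaks?
    min_sep = max(3, n // 100)
    peaks, props = signal.find_peaks(
        y,
        height=ambiguity_fraction * peak_h,
        prominence=ambiguity_fraction * peak_h,
        distance=min_sep,
    )
    if len(peaks) > 1:
        raise AmbiguousPeakError([float(T[p]) for p in peaks])

    Tm, _ = _parabolic_apex(T, y, apex_i)

    # contiguous support around the apex above the threshold
    thresh = peak_support_fraction * peak_h
    lo = apex_i
    while lo > 0 and y[lo - 1] > thresh:
        lo -= 1
    hi = apex_i
    while hi < n - 1 and y[hi + 1] > thresh:
        hi += 1
    dH = float(np.trapezoid(y[lo : hi + 1], T[lo : hi + 1]))

    left, right = _half_height_crossings(T, y, apex_i, peak_h / 2.0)
    return TransitionMetrics(
        Tm=Tm, dH=dH, dT_half=right - left, baseline=trace.baseline or None
    )


def compare_to_control(
    metrics: TransitionMetrics, control: TransitionMetrics
) -> ControlComparison:
    """ΔT_m = T_m − T_m° and ΔH/ΔH° relative to the control condition."""
    if control.dH <= 0:
        raise ValueError("control enthalpy must be positive")
    return ControlComparison(
        dTm=metrics.Tm - control.Tm, dH_ratio=metrics.dH / control.dH
    )
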