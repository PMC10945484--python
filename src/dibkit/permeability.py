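"""Osmotic water permeability (P_f) inference from droplet-pair trajectories.

The flux law is the standard osmotic-permeability definition

    dV1/dt = -P_f · v_w · π·rc² · (c2 - c1),

with instantaneous osmolarities obtained from conserved per-droplet solute
amounts and current truncated-sphere volumes. Two estimators are provided:
a linear initial-rate estimate and a full ODE least-squares fit; replicates
aggregate to mean ± SEM per experimental condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._ode import (
    CONSTANT_CONTACT_RADIUS,
    SHRINKAGE_MODES,
    UM3_PER_L,
    integrate_pair_volumes,
    volume_flux,
)
from .droplet_geometry import DropletPairState, Trajectory, truncated_sphere_volume
from .errors import FitError, UndefinedEstimateError

__all__ = [
    "OsmoticConditions",
    "PermeabilityEstimate",
    "ReplicateSummary",
    "osmotic_flux_model",
    "estimate_pf_initial_rate",
    "estimate_pf_ode_fit",
    "aggregate_condition",
    "percent_change",
]

PF_BOUNDS = (0.0, 1.0e4)  # μm/s


@dataclass(frozen=True)
class OsmoticConditions:
    """Initial osmolarities (osmol/L) of the two droplets plus constants.

    ``osmolality_1`` belongs to the droplet reported in the trajectory's
    ``R1_um`` column. Temperature is metadata only.
    """

    osmolality_1: float
    osmolality_2: float
    v_w: float = 18.0  # cm³/mol
    temperature: float = 30.0  # °C

    def __post_init__(self):
        if self.osmolality_1 < 0 or self.osmolality_2 < 0:
            raise ValueError("osmolarities must be non-negative")
        if self.v_w <= 0:
            raise ValueError("v_w must be positive")


@dataclass(frozen=True)
class PermeabilityEstimate:
    Pf: float  # μm/s
    stderr: float  # μm/s
    method: str  # "initial_rate" | "ode_fit"
    residual_rms: float  # μm³
    n_points: int

    def __post_init__(self):
        if self.Pf < 0:
            raise ValueError("Pf must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")


@dataclass(frozen=True)
class ReplicateSummary:
    mean_Pf: float
    sem: float
    n: int
    label: str = ""

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


def osmotic_flux_model(
    state: DropletPairState, c1: float, c2: float, Pf: float, v_w: float = 18.0
) -> float:
    """Instantaneous volume flux dV1/dt (μm³/s) of droplet 1.

    ``c1, c2`` are the current osmolarities (osmol/L); the flux is
    antisymmetric (dV2/dt = -dV1/dt) and vanishes when c1 = c2.
    """
    return volume_flux(Pf, state.rc, c1, c2, v_w)


def _initial_solute(traj: Trajectory, conditions: OsmoticConditions):
    V1, V2 = traj.volumes()
    n1 = conditions.osmolality_1 / UM3_PER_L * V1[0]
    n2 = conditions.osmolality_2 / UM3_PER_L * V2[0]
    return V1, V2, n1, n2


def estimate_pf_initial_rate(
    traj: Trajectory, conditions: OsmoticConditions, window: int = 5
) -> PermeabilityEstimate:
    """P_f from the initial slope of droplet-1 volume.

    Fits a line to V1(t) over the first ``window`` samples and divides the
    absolute slope by ``v_w · A(0) · |Δc(0)|``. Standard error is propagated
    from the slope's standard error.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(traj) < window:
        raise ValueError(f"trajectory has {len(traj)} < window={window} points")
    dc0 = conditions.osmolality_2 - conditions.osmolality_1
    if dc0 == 0:
        raise UndefinedEstimateError("zero initial osmotic gradient")
    V1, _ = traj.volumes()
    t = traj.time_s[:window]
    v = V1[:window]
    res = stats.linregress(t, v)
    area0 = np.pi * traj.rc_um[0] ** 2  # μm²
    denom = conditions.v_w * 1e12 * area0 * abs(dc0) / UM3_PER_L  # μm³/s per (μm/s)
    pf = abs(res.slope) / denom
    stderr = (res.stderr if np.isfinite(res.stderr) else 0.0) / denom
    fit = res.intercept + res.slope * t
    rms = float(np.sqrt(np.mean((v - fit) ** 2)))
    return PermeabilityEstimate(
        Pf=float(pf),
        stderr=float(stderr),
        method="initial_rate",
        residual_rms=rms,
        n_points=window,
    )


def estimate_pf_ode_fit(
    traj: Trajectory,
    conditions: OsmoticConditions,
    shrinkage_mode: str = CONSTANT_CONTACT_RADIUS,
    fit_initial_volume: bool = True,
) -> PermeabilityEstimate:
    """P_f by least squares between observed droplet-1 volumes and the
    forward-integrated osmotic shrinkage model.

    P_f is bounded to [0, 1e4] μm/s and initialized from the initial-rate
    estimate. Residuals are taken against *both* droplets' observed volume
    series: water conservation makes droplet 2 an independent-noise replica
    of the same transfer, which halves the estimator variance. By default
    the two initial volumes are co-fitted as nuisance parameters: anchoring
    the integration at the measured first samples would propagate their
    noise into the slope and hence into P_f. The standard error comes from
    the fit's Gauss-Newton curvature at the optimum.
    """
    if shrinkage_mode not in SHRINKAGE_MODES:
        raise ValueError(f"shrinkage_mode must be one of {SHRINKAGE_MODES}")
    if len(traj) < 3:
        raise ValueError("need at least 3 time points for an ODE fit")
    dc0 = conditions.osmolality_2 - conditions.osmolality_1
    if dc0 == 0:
        raise UndefinedEstimateError("zero initial osmotic gradient")

    V1_obs, V2_obs = traj.volumes()
    V1_0, V2_0 = float(V1_obs[0]), float(V2_obs[0])
    rc_0 = float(traj.rc_um[0])
    t = traj.time_s
    obs = np.concatenate([V1_obs, V2_obs])

    def model(pf: float, v1_0: float, v2_0: float) -> np.ndarray:
        v1, v2, _ = integrate_pair_volumes(
            v1_0,
            v2_0,
            rc_0,
            conditions.osmolality_1,
            conditions.osmolality_2,
            pf,
            conditions.v_w,
            t,
            shrinkage_mode=shrinkage_mode,
        )
        return np.concatenate([v1, v2])

    try:
        window = min(5, len(traj))
        pf0 = estimate_pf_initial_rate(traj, conditions, window=window).Pf
    except Exception:
        pf0 = 50.0
    pf0 = float(np.clip(pf0, PF_BOUNDS[0] + 1e-6, PF_BOUNDS[1] - 1.0))

    if fit_initial_volume:
        x0 = [pf0, V1_0, V2_0]
        lo = [PF_BOUNDS[0], 0.5 * V1_0, 0.5 * V2_0]
        hi = [PF_BOUNDS[1], 1.5 * V1_0, 1.5 * V2_0]
        fun = lambda p: model(p[0], p[1], p[2]) - obs
    else:
        x0, lo, hi = [pf0], [PF_BOUNDS[0]], [PF_BOUNDS[1]]
        fun = lambda p: model(p[0], V1_0, V2_0) - obs

    sol = optimize.least_squares(
        fun, x0=x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    if not sol.success:
        raise FitError(f"P_f optimisation failed: {sol.message} (status {sol.status})")
    pf = float(sol.x[0])
    resid = sol.fun
    n, k = len(resid), len(sol.x)
    rms = float(np.sqrt(np.mean(resid**2)))
    jtj = sol.jac.T @ sol.jac
    stderr = 0.0
    if n > k:
        s2 = float(resid @ resid) / (n - k)
        try:
            cov = s2 * np.linalg.inv(jtj)
            if cov[0, 0] > 0:
                stderr = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass
    return PermeabilityEstimate(
        Pf=pf, stderr=stderr, method="ode_fit", residual_rms=rms, n_points=n
    )


def aggregate_condition(
    estimates: Sequence[PermeabilityEstimate | float], label: str = ""
) -> ReplicateSummary:
    """Mean ± SEM of replicate P_f estimates (SEM = sample SD / √n; 0 for
    a single replicate)."""
    if len(estimates) == 0:
        raise ValueError("no estimates to aggregate")
    vals = np.array(
        [e.Pf if isinstance(e, PermeabilityEstimate) else float(e) for e in estimates]
    )
    n = len(vals)
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ReplicateSummary(mean_Pf=float(vals.mean()), sem=sem, n=n, label=label)


def percent_change(Pf_condition: float, Pf_control: float) -> float:
    """Signed percent change of a condition's P_f relative to control."""
    if Pf_control <= 0:
        raise ValueError("control P_f must be positive")
    return 100.0 * (Pf_condition - Pf_control) / Pf_control
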