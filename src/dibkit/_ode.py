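"""Shared forward model for osmotic water transport across a droplet
interface bilayer.

State variable is the volume of droplet 1; droplet 2 follows from water
conservation. Solute amounts per droplet are conserved, so instantaneous
osmolarities are ``c_i(t) = n_i / V_i(t)``.

Unit conventions: lengths μm, volumes μm³, time s, permeability μm/s,
water molar volume cm³/mol, osmolarity osmol/L.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .droplet_geometry import radius_from_volume, truncated_sphere_volume
from .errors import GeometryError, IntegrationError

UM3_PER_CM3 = 1.0e12  # 1 cm³ = 1e12 μm³
UM3_PER_L = 1.0e15  # 1 L = 1e15 μm³

CONSTANT_CONTACT_RADIUS = "constant_contact_radius"
CONSTANT_CONTACT_ANGLE = "constant_contact_angle"
SHRINKAGE_MODES = (CONSTANT_CONTACT_RADIUS, CONSTANT_CONTACT_ANGLE)


def volume_flux(Pf: float, rc: float, c1: float, c2: float, v_w: float) -> float:
    """dV1/dt (μm³/s) for permeability ``Pf`` (μm/s), contact radius ``rc``
    (μm), osmolarities ``c1, c2`` (osmol/L) and water molar volume ``v_w``
    (cm³/mol).

    ``dV1/dt = -Pf · v_w · π·rc² · (c2 - c1)``: water leaves the hypotonic
    droplet (the one with the lower osmolarity).
    """
    area = np.pi * rc * rc  # μm²
    v_w_um3 = v_w * UM3_PER_CM3  # μm³/mol
    dc = (c2 - c1) / UM3_PER_L  # osmol/μm³
    return -Pf * v_w_um3 * area * dc


def _contact_radius_constant_angle(
    V1: float, V2: float, theta_sum0: float, rc_guess: float
) -> float:
    """Contact radius at which the summed centre half-angles
    ``asin(rc/R1) + asin(rc/R2)`` equal their initial value, for the current
    droplet volumes."""

    def angle_sum(rc: float) -> float:
        r1 = radius_from_volume(V1, rc)
        r2 = radius_from_volume(V2, rc)
        return np.arcsin(min(rc / r1, 1.0)) + np.arcsin(min(rc / r2, 1.0))

    rc_hi = 0.999 * min(
        (3.0 * V1 / (2.0 * np.pi)) ** (1 / 3), (3.0 * V2 / (2.0 * np.pi)) ** (1 / 3)
    )
    f = lambda rc: angle_sum(rc) - theta_sum0

    # warm-started secant from the previous step's rc, falling back to brentq
    if 0 < rc_guess < rc_hi:
        try:
            rc = optimize.newton(
                f, x0=min(rc_guess, 0.98 * rc_hi), tol=1e-10 * rc_hi, maxiter=20
            )
            if 0 < rc < rc_hi and abs(f(rc)) < 1e-9:
                return float(rc)
        except (RuntimeError, ValueError, GeometryError):
            pass
    lo, hi = 1e-9 * rc_hi, rc_hi
    if f(hi) < 0:  # angle target unreachable; clamp at hemisphere limit
        return rc_hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-10 * rc_hi, rtol=1e-12))


def integrate_pair_volumes(
    V1_0: float,
    V2_0: float,
    rc_0: float,
    c1_0: float,
    c2_0: float,
    Pf: float,
    v_w: float,
    t_eval: np.ndarray,
    shrinkage_mode: str = CONSTANT_CONTACT_RADIUS,
    rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the osmotic shrinkage ODE.

    Returns ``(V1, V2, rc)`` arrays evaluated at ``t_eval`` (seconds).
    Initial osmolarities ``c1_0, c2_0`` are in osmol/L; solute amounts are
    conserved thereafter.
    """
    if shrinkage_mode not in SHRINKAGE_MODES:
        raise ValueError(f"unknown shrinkage_mode {shrinkage_mode!r}")
    t_eval = np.asarray(t_eval, dtype=float)
    n1 = c1_0 / UM3_PER_L * V1_0  # osmol
    n2 = c2_0 / UM3_PER_L * V2_0
    V_tot = V1_0 + V2_0

    theta_sum0 = None
    if shrinkage_mode == CONSTANT_CONTACT_ANGLE and rc_0 > 0:
        r1_0 = radius_from_volume(V1_0, rc_0)
        r2_0 = radius_from_volume(V2_0, rc_0)
        theta_sum0 = float(np.arcsin(rc_0 / r1_0) + np.arcsin(rc_0 / r2_0))

    def rc_of(V1: float, rc_guess: float) -> float:
        if rc_0 == 0:
            return 0.0
        if shrinkage_mode == CONSTANT_CONTACT_RADIUS:
            return rc_0
        return _contact_radius_constant_angle(V1, V_tot - V1, theta_sum0, rc_guess)

    last_rc = [rc_0]

    # geometric floor: a droplet cannot shrink past the hemisphere over a
    # fixed contact disc (constant-radius mode) or drain completely
    if shrinkage_mode == CONSTANT_CONTACT_RADIUS and rc_0 > 0:
        v_floor = 2.0 / 3.0 * np.pi * rc_0**3 * (1.0 + 1e-6)
    else:
        v_floor = 1e-6 * V_tot
    V1_min = min(v_floor, 0.5 * V1_0)
    V1_max = V_tot - min(v_floor, 0.5 * V2_0)

    def rhs(t, y):
        V1 = y[0]
        if not np.isfinite(V1):
            raise IntegrationError(f"non-finite volume V1={V1} at t={t:.6g} s")
        V1 = float(np.clip(V1, 0.5 * V1_min, 0.5 * (V1_max + V_tot)))
        V2 = V_tot - V1
        rc = rc_of(V1, last_rc[0])
        last_rc[0] = rc
        c1 = n1 / V1 * UM3_PER_L
        c2 = n2 / V2 * UM3_PER_L
        return [volume_flux(Pf, rc, c1, c2, v_w)]

    def hit_floor(t, y):
        return y[0] - V1_min

    def hit_ceiling(t, y):
        return V1_max - y[0]

    hit_floor.terminal = True
    hit_ceiling.terminal = True

    if Pf == 0 or c1_0 == c2_0:
        V1 = np.full_like(t_eval, V1_0)
    else:
        sol = solve_ivp(
            rhs,
            (float(t_eval[0]), float(t_eval[-1])),
            [V1_0],
            t_eval=t_eval,
            method="RK45",
            rtol=rtol,
            atol=rtol * V1_0,
            max_step=max((t_eval[-1] - t_eval[0]) / 20.0, 1e-6),
            events=[hit_floor, hit_ceiling],
        )
        if sol.status == -1:
            raise IntegrationError(f"ODE solver failed: {sol.message}")
        V1 = sol.y[0]
        if len(V1) < len(t_eval):
            # terminated at the geometric limit: hold the terminal volume
            pad = V1[-1] if len(V1) else (V1_min if n2 > n1 else V1_max)
            V1 = np.concatenate([V1, np.full(len(t_eval) - len(V1), pad)])
        if not np.all(np.isfinite(V1)):
            bad = int(np.flatnonzero(~np.isfinite(V1))[0])
            raise IntegrationError(
                f"non-finite volume at step {bad} (t={t_eval[bad]:.6g} s)"
            )

    V2 = V_tot - V1
    if shrinkage_mode == CONSTANT_CONTACT_RADIUS or rc_0 == 0:
        rc = np.full_like(t_eval, rc_0)
    else:
        rc = np.array(
            [
                _contact_radius_constant_angle(v1, v2, theta_sum0, rc_0)
                for v1, v2 in zip(V1, V2)
            ]
        )
    return V1, V2, rc
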