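"""Aerodynamic force extraction and lift/drag normalization.

The hydrodynamic force on the penalized wing is the volume integral of the
Brinkman forcing over the solid mask,

    F = rho * int chi/eta * (u - u_body) dA   (reaction on the body),

per unit span.  Sign convention: +x is the flight direction (opposite the
freestream), +y is up, so a positive Fx is thrust and a positive Fy is lift.

Coefficients follow the flapping-wing convention of normalizing by the peak
translational speed of the section,

    C_L = Fy / (1/2 rho V_mag^2 A),    C_D = Fx / (1/2 rho V_mag^2 A),

with A = c * (unit span).  In forward-flight mode a positive C_D is thrust
and a negative C_D a net drag.  In hovering (validation) mode the drag
coefficient instead uses the force component opposing the instantaneous
translation, sign-folded per half-stroke, so resistive drag averages to a
positive number over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["ForceRecord", "body_force", "coefficients", "records_to_frame"]


@dataclass(frozen=True)
class ForceRecord:
    """Force on the wing at one time step, per unit span."""

    t: float      # s
    tau: float    # phase f*t
    Fx: float     # N/m, +x = flight direction
    Fy: float     # N/m, +y = up
    CL: float
    CD: float


def coefficients(
    Fx: float,
    Fy: float,
    rho: float,
    V_mag: float,
    A: float,
    mode: str = "forward",
    body_velocity: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Normalize a force pair to (C_L, C_D).

    Parameters
    ----------
    Fx, Fy : float
        Force per unit span, N/m.
    rho : float
        Fluid density, kg/m^3.
    V_mag : float
        Reference speed: the wing's peak translational speed, or the inlet
        speed for static (grid-study style) cases.
    A : float
        Reference area per unit span (chord in metres).
    mode : {"forward", "validation"}
        ``forward``: C_D = Fx/qA (positive = thrust).  ``validation``:
        resistive convention; C_D is the component of -F along the
        instantaneous translation direction, requiring ``body_velocity``.
    """
    if not V_mag > 0:
        raise InvalidParameterError(f"V_mag must be positive, got {V_mag}")
    if not A > 0:
        raise InvalidParameterError(f"reference area must be positive, got {A}")
    q = 0.5 * rho * V_mag * V_mag * A
    cl = Fy / q
    if mode == "forward":
        cd = Fx / q
    elif mode == "validation":
        if body_velocity is None:
            raise InvalidParameterError(
                "validation-mode coefficients need the body velocity"
            )
        vx, vy = body_velocity
        speed = float(np.hypot(vx, vy))
        if speed > 0.0:
            cd = -(Fx * vx + Fy * vy) / (speed * q)
        else:
            cd = 0.0
    else:
        raise InvalidParameterError(f"unknown coefficient mode {mode!r}")
    return cl, cd


def body_force(state, case, t: float | None = None) -> tuple[float, float]:
    """Penalization force integral on the current state, N/m.

    Evaluates rho * sum chi/eta (u - u_body) dA from the instantaneous
    fields.  After a converged penalized step this recovers the force the
    body exerts on the fluid's momentum budget; with no solid present it is
    identically (0, 0).  The per-step records produced by the solver use the
    step's own momentum exchange and are preferred for time series.
    """
    from .solver import Simulation

    if case.profile is None:
        return (0.0, 0.0)
    sim = Simulation(case, geometry_only=True)
    tt = state.t if t is None else t
    chi_u, chi_v, ub, vb = sim.masks(tt)
    dA = sim.dx * sim.dy
    fx = sim.rho / sim.eta * float(np.sum(chi_u * (state.u - ub))) * dA
    fy = sim.rho / sim.eta * float(np.sum(chi_v * (state.v - vb))) * dA
    return fx, fy


def records_to_frame(records):
    """Force records as a pandas DataFrame (t, tau, Fx, Fy, CL, CD)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t": [r.t for r in records],
            "tau": [r.tau for r in records],
            "Fx": [r.Fx for r in records],
            "Fy": [r.Fy for r in records],
            "CL": [r.CL for r in records],
            "CD": [r.CD for r in records],
        }
    )
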