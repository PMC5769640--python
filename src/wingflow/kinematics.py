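"""Prescribed rigid-body wing kinematics.

Two motion modes are supported:

* ``forward-flight`` — bee-like flapping rendered in 2D: the stroke (yaw) and
  deviation (roll) amplitudes become x/y translations of the wing section at
  the pivot radius r0, while the pitch angle theta3 stays angular.  With phase
  shifts zero, the section follows::

      x(t)      = r0 * theta1A[rad] * cos(w t + phi1)
      y(t)      = r0 * theta2A[rad] * cos(w t + phi2)
      theta3(t) = theta3A * sin(w t)

  so the cycle starts (tau = f t = 0) at zero incidence and zero translational
  velocity, reaches peak pitch and peak speed at mid-upstroke (tau = 0.25),
  and returns to zero incidence with zero speed at stroke reversal
  (tau = 0.5).

* ``hover-validation`` — the hovering-plate benchmark (a flat plate swept
  horizontally in still oil inside a tank).  The published phase phi1 = pi/2 is
  the 90 degree pitch-translation offset of normal hovering, so the
  translation is measured relative to the pitch sinusoid::

      x(t)              = r0 * theta1A[rad] * cos(w t + phi1 - pi/2)
      angle-from-vertical = theta3A * sin(w t)

  With phi1 = pi/2 the plate starts at the right end of the stroke, travels
  left during 0 < tau < 0.5 while near-vertical at the reversals and inclined
  theta3A from vertical at mid-stroke, then returns.

Degrees at the API boundary (amplitudes as published), radians internally.
Lengths in mm, velocities in m/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "KinematicsSpec",
    "WingMotionSample",
    "forward_flight_spec",
    "hover_validation_spec",
    "pitch_angle",
    "placement_angle",
    "placement_rate",
    "translation",
    "body_velocity",
    "motion_sample",
    "validation_motion",
    "v_kin_max",
    "theta2A_for_speed",
    "reynolds",
    "export_motion_trace",
]

_MM = 1e-3  # mm -> m

#: roll-amplitude lookup: theta2A (deg) against forward flight speed (m/s)
THETA2A_TABLE_SPEEDS = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
THETA2A_TABLE_DEG = np.array([10.0, 15.0, 20.0, 24.0, 26.0])


@dataclass(frozen=True)
class KinematicsSpec:
    """Flap frequency, angular amplitudes, phases and pivot radius.

    Parameters
    ----------
    f : float
        Flap frequency, Hz.
    theta1A, theta2A, theta3A : float
        Stroke, deviation and pitch amplitudes, degrees.
    phi1, phi2 : float
        Phase shifts of the x and y translations, radians.  In
        ``hover-validation`` mode they are measured relative to the pitch
        sinusoid (the conventional hovering offset pi/2 gives a cos stroke).
    r0 : float
        Pivot-to-section distance, mm.
    mode : str
        ``"forward-flight"`` or ``"hover-validation"``.
    """

    f: float
    theta1A: float
    theta2A: float
    theta3A: float
    r0: float
    phi1: float = 0.0
    phi2: float = 0.0
    mode: str = "forward-flight"

    def __post_init__(self):
        if not self.f > 0:
            raise InvalidParameterError(f"flap frequency must be positive, got {self.f}")
        for nm in ("theta1A", "theta2A", "theta3A"):
            if getattr(self, nm) < 0:
                raise InvalidParameterError(f"{nm} must be non-negative")
        if self.theta1A > 180.0:
            raise InvalidParameterError("theta1A must not exceed 180 degrees")
        if not self.r0 > 0:
            raise InvalidParameterError(f"r0 must be positive, got {self.r0}")
        if self.mode not in ("forward-flight", "hover-validation"):
            raise InvalidParameterError(f"unknown kinematics mode {self.mode!r}")

    @property
    def omega(self) -> float:
        """Angular flap frequency, rad/s."""
        return 2.0 * math.pi * self.f

    @property
    def _phi1_eff(self) -> float:
        return self.phi1 - 0.5 * math.pi if self.mode == "hover-validation" else self.phi1

    @property
    def _phi2_eff(self) -> float:
        return self.phi2 - 0.5 * math.pi if self.mode == "hover-validation" else self.phi2


@dataclass(frozen=True)
class WingMotionSample:
    """Full kinematic state of the section at one instant."""

    t: float          # s
    tau: float        # dimensionless phase f*t
    x: float          # mm
    y: float          # mm
    theta3: float     # pitch, deg
    vx: float         # m/s
    vy: float         # m/s
    omega3: float     # pitch rate, rad/s


def forward_flight_spec(V_inf: float | None = None, **overrides) -> KinematicsSpec:
    """Bee forward-flight kinematics: f=150 Hz, theta1A=110 deg, theta3A=24 deg,
    r0=6.61 mm; theta2A from the speed table when ``V_inf`` is given."""
    kw = dict(
        f=150.0,
        theta1A=110.0,
        theta2A=theta2A_for_speed(V_inf) if V_inf is not None else 0.0,
        theta3A=24.0,
        r0=6.61,
        mode="forward-flight",
    )
    kw.update(overrides)
    return KinematicsSpec(**kw)


def hover_validation_spec(**overrides) -> KinematicsSpec:
    """Hovering-plate benchmark kinematics: f=0.25 Hz, r=162.5 mm,
    theta1A=23.5 deg, theta2A=0, theta3A=45 deg, phi1=pi/2, phi2=0."""
    kw = dict(
        f=0.25,
        theta1A=23.5,
        theta2A=0.0,
        theta3A=45.0,
        r0=162.5,
        phi1=0.5 * math.pi,
        phi2=0.0,
        mode="hover-validation",
    )
    kw.update(overrides)
    return KinematicsSpec(**kw)


# ---------------------------------------------------------------------------
# positions
# ---------------------------------------------------------------------------

def pitch_angle(t, spec: KinematicsSpec):
    """Pitch angle theta3 in degrees: theta3A * sin(w t).

    Zero at tau=0, +theta3A at tau=0.25, zero again at tau=0.5.  In
    hover-validation mode this is the inclination from vertical.
    """
    return spec.theta3A * np.sin(spec.omega * np.asarray(t, dtype=float))


def placement_angle(t, spec: KinematicsSpec):
    """Orientation of the section chord from the +x axis, degrees (CCW).

    Forward flight: the freestream arrives from +x (the leading edge points
    into it), so a positive angle of incidence -- nose raised into the
    oncoming flow, the lift-producing sense -- is a *clockwise* geometric
    rotation; the chord angle is minus the pitch angle.
    Hover validation: 90 degrees plus the inclination from vertical (the
    plate hangs near-vertical and tilts its top edge into the motion).
    """
    th = pitch_angle(t, spec)
    if spec.mode == "hover-validation":
        return 90.0 + th
    return -th


def placement_rate(t, spec: KinematicsSpec):
    """d/dt of :func:`placement_angle` in rad/s (rigid-body spin rate)."""
    _, _, om3 = body_velocity(t, spec)
    if spec.mode == "hover-validation":
        return om3
    return -om3


def translation(t, spec: KinematicsSpec):
    """Section translation (x, y) in mm at time t (s)."""
    t = np.asarray(t, dtype=float)
    ax = spec.r0 * math.radians(spec.theta1A)
    ay = spec.r0 * math.radians(spec.theta2A)
    x = ax * np.cos(spec.omega * t + spec._phi1_eff)
    y = ay * np.cos(spec.omega * t + spec._phi2_eff)
    return x, y


def body_velocity(t, spec: KinematicsSpec):
    """Analytic (vx, vy, omega3): translational velocity in m/s, pitch rate rad/s."""
    t = np.asarray(t, dtype=float)
    w = spec.omega
    ax = spec.r0 * math.radians(spec.theta1A) * _MM
    ay = spec.r0 * math.radians(spec.theta2A) * _MM
    vx = -ax * w * np.sin(w * t + spec._phi1_eff)
    vy = -ay * w * np.sin(w * t + spec._phi2_eff)
    om3 = math.radians(spec.theta3A) * w * np.cos(w * t)
    return vx, vy, om3


def motion_sample(t: float, spec: KinematicsSpec) -> WingMotionSample:
    """Bundle position, pitch and velocities at one instant."""
    x, y = translation(t, spec)
    vx, vy, om3 = body_velocity(t, spec)
    return WingMotionSample(
        t=float(t),
        tau=float(spec.f * t),
        x=float(x),
        y=float(y),
        theta3=float(pitch_angle(t, spec)),
        vx=float(vx),
        vy=float(vy),
        omega3=float(om3),
    )


def validation_motion(t: float, spec: KinematicsSpec) -> WingMotionSample:
    """Hovering-plate motion sample; requires ``mode='hover-validation'``.

    x = r0*theta1A[rad]*cos(w t) for the published phi1=pi/2 (leftward travel
    during 0<tau<0.5), y = 0; ``theta3`` is the inclination from vertical.
    """
    if spec.mode != "hover-validation":
        raise InvalidParameterError(
            f"validation_motion requires mode='hover-validation', got {spec.mode!r}"
        )
    return motion_sample(t, spec)


# ---------------------------------------------------------------------------
# derived scalars
# ---------------------------------------------------------------------------

def v_kin_max(spec: KinematicsSpec, n_samples: int = 20000) -> float:
    """Maximum translational speed of the section over one period, m/s.

    Computed by dense sampling of sqrt(vx^2 + vy^2); with equal phases this
    equals r0*w*sqrt(theta1A^2 + theta2A^2) in radians.
    """
    t = np.arange(n_samples) / (n_samples * spec.f)
    vx, vy, _ = body_velocity(t, spec)
    return float(np.max(np.hypot(vx, vy)))


def theta2A_for_speed(V_inf: float) -> float:
    """Deviation amplitude theta2A (deg) for a forward speed in [1, 5] m/s.

    Exact table values at integer speeds (10/15/20/24/26 deg at 1..5 m/s),
    linear interpolation between.
    """
    if not (THETA2A_TABLE_SPEEDS[0] <= V_inf <= THETA2A_TABLE_SPEEDS[-1]):
        raise InvalidParameterError(
            f"flight speed {V_inf} m/s outside the tabulated range [1, 5] m/s"
        )
    return float(np.interp(V_inf, THETA2A_TABLE_SPEEDS, THETA2A_TABLE_DEG))


def reynolds(spec: KinematicsSpec, V_inf: float, rho: float, mu: float, c: float) -> float:
    """Re = rho*(V_kin + V_inf)*c/mu with V_kin the peak kinematic speed.

    ``c`` in metres; rho, mu positive.
    """
    if not (rho > 0 and mu > 0):
        raise InvalidParameterError("fluid properties must be positive")
    if not c > 0:
        raise InvalidParameterError("chord must be positive")
    return rho * (v_kin_max(spec) + V_inf) * c / mu


def with_speed(spec: KinematicsSpec, V_inf: float) -> KinematicsSpec:
    """Copy of a forward-flight spec with theta2A looked up for ``V_inf``."""
    return replace(spec, theta2A=theta2A_for_speed(V_inf))


# ---------------------------------------------------------------------------
# trace export
# ---------------------------------------------------------------------------

def export_motion_trace(path, spec: KinematicsSpec, n_cycles: float = 1.0,
                        n_per_cycle: int = 400) -> None:
    """Write a CSV motion trace (t, tau, x, y, theta3, vx, vy, omega3)."""
    n = int(round(n_cycles * n_per_cycle))
    t = np.arange(n + 1) / (n_per_cycle * spec.f)
    x, y = translation(t, spec)
    vx, vy, om3 = body_velocity(t, spec)
    th = pitch_angle(t, spec)
    import pandas as pd

    df = pd.DataFrame(
        {
            "t": t,
            "tau": spec.f * t,
            "x_mm": x,
            "y_mm": y,
            "theta3_deg": th,
            "vx": vx,
            "vy": vy,
            "omega3": om3,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
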