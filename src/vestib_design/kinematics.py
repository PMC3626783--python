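"""Head-rotation kinematics for the two-turn diagnostic maneuver.

The maneuver is a positive pitch (head back) from the upright position
followed by a positive roll (head to the right), each lasting ``delta_t``
seconds and sweeping an angle ``alpha``.  Each turn is a rest-to-rest cubic
spline: angular velocity vanishes at both ends of both turns, which is how a
clinician actually moves a patient's head.

Angles are radians throughout; degrees appear only in reports.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ManeuverPoint",
    "TurnPhase",
    "turn_angle",
    "turn_angular_derivatives",
    "rotation_matrix",
    "trajectory_table",
]

#: Soft design-space bounds (duration seconds, angle radians).
DESIGN_BOUNDS = ((0.5, 1.5), (math.pi / 6, math.pi / 2))


@dataclass(frozen=True)
class ManeuverPoint:
    """One candidate maneuver z = (delta_t, alpha).

    Parameters
    ----------
    delta_t:
        Duration of each of the two turns, seconds.  Must be positive.
    alpha:
        Angle swept by each turn, radians in (0, pi/2].
    """

    delta_t: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be positive, got {self.delta_t}")
        if not 0 < self.alpha <= math.pi / 2 + 1e-12:
            raise ValueError(
                f"alpha must lie in (0, pi/2] radians, got {self.alpha}"
            )

    @property
    def alpha_deg(self) -> float:
        return math.degrees(self.alpha)

    def as_tuple(self) -> tuple[float, float]:
        return (self.delta_t, self.alpha)


class TurnPhase(enum.Enum):
    """Which of the two turns is under way at a given maneuver-local time."""

    PITCH = "pitch"   # first turn, t <= delta_t
    ROLL = "roll"     # second turn, delta_t < t <= 2 delta_t


def _check_time(t: float, m: ManeuverPoint) -> None:
    if not 0 <= t <= 2 * m.delta_t + 1e-12:
        raise ValueError(
            f"time {t} outside maneuver window [0, {2 * m.delta_t}]"
        )


def phase_of(t: float, m: ManeuverPoint) -> TurnPhase:
    _check_time(t, m)
    return TurnPhase.PITCH if t <= m.delta_t else TurnPhase.ROLL


def turn_angle(t: float, m: ManeuverPoint) -> float:
    """Turn angle Omega(t) of the active phase, radians.

    Phase 1 (pitch, ``t <= delta_t``)::

        Omega_1(t) = 3 a t^2/dt^2 - 2 a t^3/dt^3

    rises from 0 to alpha.  Phase 2 (roll, ``delta_t < t <= 2 delta_t``)::

        Omega_2(t) = 5a - 12a t/dt + 9a t^2/dt^2 - 2a t^3/dt^3

    measures the roll's own angle: it is 0 at ``t = delta_t`` and alpha at
    ``t = 2 delta_t``.  The completed pitch enters the frame change only
    through the constant alpha rotation in :func:`rotation_matrix`.
    """
    _check_time(t, m)
    if t <= m.delta_t:
        return float(phase1_angle(t, m.delta_t, m.alpha))
    return float(phase2_angle(t, m.delta_t, m.alpha))


def phase1_angle(t, dt, alpha):
    u = np.asarray(t) / dt
    return alpha * u * u * (3 - 2 * u)


def phase2_angle(t, dt, alpha):
    u = np.asarray(t) / dt
    return alpha * (5 + u * (-12 + u * (9 - 2 * u)))


def phase2_velocity(t, dt, alpha):
    u = np.asarray(t) / dt
    return alpha / dt * (-12 + u * (18 - 6 * u))


def phase2_acceleration(t, dt, alpha):
    """Omega_2''(t) = 18 a/dt^2 - 12 a t/dt^3; vanishes at t = 1.5 dt."""
    t = np.asarray(t)
    return 18 * alpha / dt**2 - 12 * alpha * t / dt**3


def turn_angular_derivatives(t: float, m: ManeuverPoint) -> tuple[float, float]:
    """Angular velocity (rad/s) and acceleration (rad/s^2) at time ``t``."""
    _check_time(t, m)
    dt, a = m.delta_t, m.alpha
    if t <= dt:
        u = t / dt
        vel = 6 * a / dt * u * (1 - u)
        acc = 6 * a / dt**2 * (1 - 2 * u)
    else:
        vel = float(phase2_velocity(t, dt, a))
        acc = float(phase2_acceleration(t, dt, a))
    return vel, acc


def _pitch_matrix(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _roll_matrix(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_matrix(t: float, m: ManeuverPoint) -> np.ndarray:
    """Head-fixed to inertial frame change M(t), a proper rotation.

    For the pitch phase M1(t) is a rotation by Omega_1(t) about the y axis.
    For the roll phase M2(t) composes the running roll with the completed
    pitch: M2(t) = Roll(Omega_2(t)) @ Pitch(alpha), so at t = delta_t (where
    Omega_2 = 0) it equals the pure pitch-by-alpha matrix.
    """
    _check_time(t, m)
    if t <= m.delta_t:
        return _pitch_matrix(turn_angle(t, m))
    return _roll_matrix(turn_angle(t, m)) @ _pitch_matrix(m.alpha)


def trajectory_table(m: ManeuverPoint, n: int = 201):
    """Sampled trajectory as a DataFrame (t_s, omega_rad, omega_dot,
    omega_ddot, phase), e.g. for a CSV dump."""
    import pandas as pd

    ts = np.linspace(0.0, 2 * m.delta_t, n)
    rows = []
    for t in ts:
        vel, acc = turn_angular_derivatives(t, m)
        rows.append(
            (t, turn_angle(t, m), vel, acc, phase_of(t, m).value)
        )
    return pd.DataFrame(
        rows, columns=["t_s", "omega_rad", "omega_dot", "omega_ddot", "phase"]
    )
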