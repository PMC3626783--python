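"""Approximate designs, Fisher information and optimality criteria.

An approximate design is a probability measure on the maneuver space: a set
of support points z_i = (delta_t, alpha) with weights p_i summing to one.
For the two-parameter response model the information matrix is

    M(xi, theta) = sum_i p_i f(z_i) f(z_i)^T,

with f the sensitivity vector of the response.  D-optimality minimises
det(M)^(-1/m) (confidence-ellipsoid volume, m = 2); c-optimality minimises
the variance c^T M^{-1} c of a linear parameter combination.  A design is
D-optimal iff its generalized variance d(z) = f(z)^T M^{-1} f(z) never
exceeds m on the design space, with equality at the support (equivalence
theorem).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinematics import ManeuverPoint
from .model import (
    NOMINAL_THETA,
    ParameterVector,
    PhysicalConstants,
    sensitivity_grid,
)

__all__ = [
    "Design",
    "information_matrix",
    "d_criterion",
    "c_criterion",
    "generalized_variance",
    "check_equivalence_D",
    "EquivalenceVerdict",
    "d_efficiency",
    "c_efficiency",
    "apportion",
]

N_PARAMS = 2
_WEIGHT_TOL = 1e-10


@dataclass(frozen=True)
class Design:
    """Support points with weights (an approximate design)."""

    points: tuple[ManeuverPoint, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.points) != len(self.weights) or not self.points:
            raise ValueError("need equally many points and weights, >= 1")
        w = np.asarray(self.weights, float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if len({p.as_tuple() for p in self.points}) != len(self.points):
            raise ValueError("support points must be distinct")

    @classmethod
    def from_arrays(cls, points, weights) -> "Design":
        pts = tuple(
            p if isinstance(p, ManeuverPoint) else ManeuverPoint(*p)
            for p in points
        )
        w = np.asarray(weights, float)
        return cls(pts, tuple(w / w.sum()))

    def sensitivities(
        self,
        theta: ParameterVector = NOMINAL_THETA,
        k: PhysicalConstants = PhysicalConstants(),
        forcing_window: str = "literal",
    ) -> np.ndarray:
        dts = [p.delta_t for p in self.points]
        als = [p.alpha for p in self.points]
        return sensitivity_grid(dts, als, theta, k,
                                forcing_window=forcing_window)

    def table(self, n_total: int | None = None):
        """DataFrame rendering (degrees at the I/O boundary only)."""
        import pandas as pd

        d = {
            "delta_t_s": [p.delta_t for p in self.points],
            "alpha_rad": [p.alpha for p in self.points],
            "alpha_deg": [p.alpha_deg for p in self.points],
            "weight": list(self.weights),
        }
        if n_total is not None:
            d[f"replicates_for_N{n_total}"] = apportion(self, n_total)
        return pd.DataFrame(d)


def information_matrix(
    d: Design,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    forcing_window: str = "literal",
) -> np.ndarray:
    """M(xi, theta) = sum_i p_i f(z_i) f(z_i)^T (2x2, symmetric PSD)."""
    f = d.sensitivities(theta, k, forcing_window)
    w = np.asarray(d.weights)
    m = (f * w[:, None]).T @ f
    return 0.5 * (m + m.T)


def _is_singular(m: np.ndarray) -> bool:
    # 2x2 PSD: relative determinant test
    tr = np.trace(m)
    return tr <= 0 or np.linalg.det(m) <= 1e-12 * tr * tr


def d_criterion(m_or_design, theta=NOMINAL_THETA, k=PhysicalConstants(),
                forcing_window: str = "literal") -> float:
    """Phi_D = det(M)^(-1/2) for m = 2 parameters; +inf when singular."""
    m = _as_matrix(m_or_design, theta, k, forcing_window)
    det = np.linalg.det(m)
    if det <= 0 or _is_singular(m):
        return math.inf
    return float(det ** (-1.0 / N_PARAMS))


def c_criterion(m_or_design, c, theta=NOMINAL_THETA, k=PhysicalConstants(),
                forcing_window: str = "literal") -> float:
    """Phi_c = c^T M^- c via generalized inverse; +inf when c is not in the
    range of M (the combination is not estimable under the design)."""
    m = _as_matrix(m_or_design, theta, k, forcing_window)
    c = np.asarray(c, float)
    if _is_singular(m):
        minv = np.linalg.pinv(m)
        resid = c - m @ (minv @ c)
        if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(c), 1e-300):
            return math.inf
        return float(c @ minv @ c)
    return float(c @ np.linalg.solve(m, c))


def _as_matrix(m_or_design, theta, k, forcing_window) -> np.ndarray:
    if isinstance(m_or_design, Design):
        return information_matrix(m_or_design, theta, k, forcing_window)
    return np.asarray(m_or_design, float)


def generalized_variance(
    z: ManeuverPoint,
    d: Design,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    forcing_window: str = "literal",
) -> float:
    """d(z) = f(z)^T M^{-1}(xi, theta) f(z) (standardized prediction
    variance)."""
    m = information_matrix(d, theta, k, forcing_window)
    if _is_singular(m):
        raise np.linalg.LinAlgError(
            "information matrix singular; generalized variance undefined"
        )
    f = sensitivity_grid(z.delta_t, z.alpha, theta, k,
                         forcing_window=forcing_window)
    return float(f @ np.linalg.solve(m, f))


@dataclass(frozen=True)
class EquivalenceVerdict:
    """Outcome of an equivalence-theorem check for D-optimality."""

    passed: bool
    applicable: bool
    max_violation: float
    worst_point: ManeuverPoint | None
    support_max_deviation: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_equivalence_D(
    d: Design,
    candidates,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    tol: float = 1e-6,
    forcing_window: str = "literal",
) -> EquivalenceVerdict:
    """Verify d(z) <= m + tol over ``candidates`` and |d(z_i) - m| <= tol at
    the support.  Singular designs are flagged as not applicable."""
    m = information_matrix(d, theta, k, forcing_window)
    if _is_singular(m):
        return EquivalenceVerdict(False, False, math.inf, None, math.inf)
    minv = np.linalg.inv(m)
    cands = [c if isinstance(c, ManeuverPoint) else ManeuverPoint(*c)
             for c in candidates]
    f = sensitivity_grid([c.delta_t for c in cands],
                         [c.alpha for c in cands], theta, k,
                         forcing_window=forcing_window)
    gv = np.einsum("ij,jk,ik->i", f, minv, f)
    worst = int(np.argmax(gv))
    max_viol = float(gv[worst] - N_PARAMS)
    fs = d.sensitivities(theta, k, forcing_window)
    gv_sup = np.einsum("ij,jk,ik->i", fs, minv, fs)
    sup_dev = float(np.max(np.abs(gv_sup - N_PARAMS)))
    passed = max_viol <= tol and sup_dev <= tol
    return EquivalenceVerdict(passed, True, max_viol, cands[worst], sup_dev)


def d_efficiency(
    d: Design,
    reference: Design,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    forcing_window: str = "literal",
) -> float:
    """Phi_D(reference) / Phi_D(d), both at ``theta``.

    Equals 1 when d matches the reference criterion value; < 1 when the
    reference (e.g. the design re-optimised at the true theta) is better.
    """
    num = d_criterion(reference, theta, k, forcing_window)
    den = d_criterion(d, theta, k, forcing_window)
    if math.isinf(den):
        return 0.0
    return num / den


def c_efficiency(
    d_D: Design,
    d_c: Design,
    c,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    forcing_window: str = "literal",
) -> float:
    """c^T M^{-1}(d_c) c / c^T M^{-1}(d_D) c: how well the D-optimal design
    estimates the combination c compared with the dedicated c-optimal one."""
    num = c_criterion(d_c, c, theta, k, forcing_window)
    den = c_criterion(d_D, c, theta, k, forcing_window)
    if math.isinf(den):
        return 0.0
    return num / den


def apportion(d: Design, n_total: int) -> list[int]:
    """Round weights to integer replicate counts summing to ``n_total``.

    Largest-remainder rounding with every support point guaranteed at least
    one replicate; e.g. weights (0.47, 0.16, 0.37) at N = 100 give
    (47, 16, 37).
    """
    kk = len(d.points)
    if n_total < kk:
        raise ValueError(
            f"cannot allocate {n_total} maneuvers over {kk} support points"
        )
    w = np.asarray(d.weights, float)
    ideal = w * n_total
    base = np.floor(ideal).astype(int)
    rem = ideal - base
    short = n_total - base.sum()
    # hand out the leftover to the largest remainders (ties: lower index)
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1
    # guarantee >= 1 by taking from the largest counts
    while np.any(base == 0):
        base[int(np.argmax(base))] -= 1
        base[int(np.argmin(base))] += 1
    return [int(x) for x in base]
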