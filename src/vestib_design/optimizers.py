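"""Search algorithms for D- and c-optimal maneuver designs.

D-optimal weights on a finite grid are found with the multiplicative
algorithm (w_i <- w_i d(z_i)/m), which is monotone and converges to the
equivalence-theorem optimum.  On the continuous rectangle a Fedorov-Wynn
exchange adds the worst equivalence-violating point, re-optimises weights
and collapses near-duplicate supports.  c-optimal designs come from the
Elfving construction: intersect the ray along c with the boundary of the
convex hull of the symmetrized sensitivity curve {f, -f}; the generating
points of the cut edge are the support, the convex coefficients the weights,
and Phi_c = (|c| / |c*|)^2.  A direct nested minimisation over <= 2-point
designs serves as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull

from .design import Design, N_PARAMS, information_matrix
from .kinematics import ManeuverPoint
from .model import NOMINAL_THETA, ParameterVector, PhysicalConstants, sensitivity_grid

__all__ = [
    "DesignSpace",
    "ElfvingSet",
    "d_optimal_finite",
    "d_optimal_continuous",
    "build_elfving_set",
    "c_optimal_elfving",
    "c_optimal_direct",
]

DEFAULT_DT_GRID = (0.5, 1.0, 1.5)
DEFAULT_ALPHA_GRID = (
    math.pi / 6, math.pi / 4, math.pi / 3, 5 * math.pi / 12, math.pi / 2,
)
DEFAULT_BOUNDS = ((0.5, 1.5), (math.pi / 6, math.pi / 2))
_MULTISTART_SEED = 20130319


@dataclass(frozen=True)
class DesignSpace:
    """Finite grid or continuous rectangle of candidate maneuvers."""

    mode: str = "finite"
    dt_grid: tuple[float, ...] = DEFAULT_DT_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if self.mode not in ("finite", "continuous"):
            raise ValueError("mode must be 'finite' or 'continuous'")
        (tl, th), (al, ah) = self.bounds
        if not (tl < th and al < ah):
            raise ValueError("bounds must be ordered")
        if self.mode == "finite":
            for dt in self.dt_grid:
                if not tl <= dt <= th:
                    raise ValueError(f"grid duration {dt} outside bounds")
            for a in self.alpha_grid:
                if not al - 1e-12 <= a <= ah + 1e-12:
                    raise ValueError(f"grid angle {a} outside bounds")

    def grid_points(self) -> list[ManeuverPoint]:
        return [ManeuverPoint(dt, a)
                for dt in self.dt_grid for a in self.alpha_grid]

    def sample(self, n_dt: int, n_alpha: int) -> tuple[np.ndarray, np.ndarray]:
        (tl, th), (al, ah) = self.bounds
        dts, als = np.meshgrid(
            np.linspace(tl, th, n_dt), np.linspace(al, ah, n_alpha),
            indexing="ij",
        )
        return dts.ravel(), als.ravel()


def _multiplicative_weights(f, w0=None, tol=1e-9, max_iter=200_000):
    """Multiplicative D-optimal weight ascent on fixed sensitivity rows."""
    f = np.asarray(f, float)
    n = len(f)
    w = np.full(n, 1.0 / n) if w0 is None else np.asarray(w0, float)
    for _ in range(max_iter):
        m = (f * w[:, None]).T @ f
        try:
            minv = np.linalg.inv(m)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "sensitivity vectors do not span 2 dimensions; "
                "the grid cannot identify both parameters"
            ) from exc
        gv = np.einsum("ij,jk,ik->i", f, minv, f)
        if gv.max() - N_PARAMS <= tol:
            break
        w = w * gv / N_PARAMS
        w /= w.sum()
    return w


def _prune(points, weights, min_weight=1e-6):
    keep = np.asarray(weights) >= min_weight
    pts = [p for p, k in zip(points, keep) if k]
    w = np.asarray(weights)[keep]
    return pts, w / w.sum()


def d_optimal_finite(
    space: DesignSpace,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    *,
    tol: float = 1e-9,
    forcing_window: str = "literal",
) -> Design:
    """D-optimal approximate design on the finite grid.

    Deterministic: starts from uniform weights, runs the multiplicative
    algorithm to the equivalence-theorem tolerance, prunes weights < 1e-6.
    """
    if space.mode != "finite":
        raise ValueError("d_optimal_finite needs a finite design space")
    pts = space.grid_points()
    if len(pts) < 2:
        raise ValueError("need at least two grid points")
    f = sensitivity_grid([p.delta_t for p in pts], [p.alpha for p in pts],
                         theta, k, forcing_window=forcing_window)
    rank = np.linalg.matrix_rank(f, tol=1e-10 * np.abs(f).max())
    if rank < N_PARAMS:
        raise ValueError("all sensitivity vectors collinear: not identifiable")
    w = _multiplicative_weights(f, tol=tol)
    pts, w = _prune(pts, w)
    return Design.from_arrays(pts, w)


def _collapse_clusters(points, weights, space, merge_tol=1e-3):
    """Merge supports closer than merge_tol in bounds-normalised coords."""
    (tl, th), (al, ah) = space.bounds
    scale = np.array([th - tl, ah - al])
    pts = [np.array(p.as_tuple()) for p in points]
    w = list(weights)
    merged = True
    while merged:
        merged = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm((pts[i] - pts[j]) / scale) < merge_tol:
                    wt = w[i] + w[j]
                    pts[i] = (w[i] * pts[i] + w[j] * pts[j]) / wt
                    w[i] = wt
                    del pts[j], w[j]
                    merged = True
                    break
            if merged:
                break
    return [ManeuverPoint(*p) for p in pts], np.asarray(w)


def _worst_point(minv, space, theta, k, forcing_window, n_coarse=24):
    """Maximise the generalized variance over the rectangle (multistart)."""
    (tl, th), (al, ah) = space.bounds

    def neg_gv(x):
        f = sensitivity_grid(x[0], x[1], theta, k,
                             forcing_window=forcing_window)
        return -float(f @ minv @ f)

    dts, als = space.sample(n_coarse, n_coarse)
    f = sensitivity_grid(dts, als, theta, k, forcing_window=forcing_window)
    gv = np.einsum("ij,jk,ik->i", f, minv, f)
    starts = np.argsort(gv)[-4:]
    best_x, best_v = None, np.inf
    for idx in starts:
        res = minimize(neg_gv, x0=[dts[idx], als[idx]], method="L-BFGS-B",
                       bounds=[(tl, th), (al, ah)])
        if res.fun < best_v:
            best_x, best_v = res.x, res.fun
    return ManeuverPoint(*best_x), -best_v


def _polish_supports(points, weights, space, theta, k, forcing_window):
    """Joint local refinement of support locations and weights (max log det
    M) starting from the exchange iterate; cleans up split supports."""
    n = len(points)
    (tl, th), (al, ah) = space.bounds
    z0 = np.array([p.as_tuple() for p in points]).ravel()
    x0 = np.concatenate([z0, np.log(np.asarray(weights))])

    def neg_logdet(x):
        zs = x[:2 * n].reshape(n, 2)
        w = np.exp(x[2 * n:] - x[2 * n:].max())
        w = w / w.sum()
        f = sensitivity_grid(zs[:, 0], zs[:, 1], theta, k,
                             forcing_window=forcing_window)
        m = (f * w[:, None]).T @ f
        sign, logdet = np.linalg.slogdet(m)
        return np.inf if sign <= 0 else -logdet

    bounds = [(tl, th), (al, ah)] * n + [(-16.0, 1.0)] * n
    res = minimize(neg_logdet, x0, method="L-BFGS-B", bounds=bounds)
    zs = res.x[:2 * n].reshape(n, 2)
    w = np.exp(res.x[2 * n:] - res.x[2 * n:].max())
    return [ManeuverPoint(*z) for z in zs], w / w.sum()


def d_optimal_continuous(
    space: DesignSpace,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    *,
    tol: float = 1e-6,
    max_rounds: int = 60,
    forcing_window: str = "literal",
) -> Design:
    """Fedorov-Wynn exchange over the continuous rectangle.

    Alternates adding the worst equivalence-violating point with
    multiplicative weight re-optimisation and cluster collapsing; once the
    generalized variance is nearly flat, the supports and weights get a
    joint local polish before the final equivalence check.
    """
    if space.mode != "continuous":
        raise ValueError("d_optimal_continuous needs a continuous space")
    # start from a coarse grid covering the rectangle (corners included)
    dts, als = space.sample(4, 4)
    points = [ManeuverPoint(dt, a) for dt, a in zip(dts, als)]
    weights = np.full(len(points), 1.0 / len(points))

    def reweight(pts):
        f = sensitivity_grid([p.delta_t for p in pts],
                             [p.alpha for p in pts], theta, k,
                             forcing_window=forcing_window)
        return _multiplicative_weights(f, tol=0.1 * tol)

    for _ in range(max_rounds):
        weights = reweight(points)
        points, weights = _prune(points, weights, min_weight=1e-5)
        points, weights = _collapse_clusters(points, weights, space)
        d = Design.from_arrays(points, weights)
        minv = np.linalg.inv(information_matrix(d, theta, k, forcing_window))
        z, gv = _worst_point(minv, space, theta, k, forcing_window)
        if gv <= N_PARAMS + tol:
            # near-converged: refine locations, merge split supports (the
            # equivalence theorem re-validates the merge), tidy weights
            points, weights = _polish_supports(points, weights, space,
                                               theta, k, forcing_window)
            points, weights = _prune(points, weights, min_weight=1e-4)
            points, weights = _collapse_clusters(points, weights, space,
                                                 merge_tol=5e-2)
            weights = reweight(points)
            points, weights = _prune(points, weights, min_weight=1e-4)
            d = Design.from_arrays(points, weights)
            minv = np.linalg.inv(
                information_matrix(d, theta, k, forcing_window))
            z, gv = _worst_point(minv, space, theta, k, forcing_window)
            if gv <= N_PARAMS + tol:
                return d
        if all(z.as_tuple() != p.as_tuple() for p in points):
            points = list(points) + [z]
            weights = np.append(weights * (1 - 1.0 / (len(points))),
                                1.0 / len(points))
    import warnings

    warnings.warn(
        f"exchange did not reach max gv <= {N_PARAMS} + {tol} in "
        f"{max_rounds} rounds; returning best found"
    )
    return d


@dataclass(frozen=True)
class ElfvingSet:
    """Convex hull of the symmetrized sensitivity curve {f, -f}.

    ``vertices`` are hull vertices in counter-clockwise order; each carries a
    back-pointer (delta_t, alpha, sign) to the generating maneuver.
    """

    vertices: np.ndarray                   # (v, 2)
    generators: tuple[tuple[float, float, int], ...]
    hull: ConvexHull = field(repr=False)
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS

    def boundary_cut(self, c) -> tuple[np.ndarray, float]:
        """Intersection c* of the ray {t c : t > 0} with the hull boundary.

        Returns (c*, facet index).  The origin is interior (central
        symmetry + identifiability), so the cut exists for any c != 0.
        """
        c = np.asarray(c, float)
        norm = np.linalg.norm(c)
        if norm == 0:
            raise ValueError("c must be nonzero")
        chat = c / norm
        a, b = self.hull.equations[:, :2], -self.hull.equations[:, 2]
        proj = a @ chat
        with np.errstate(divide="ignore"):
            t = np.where(proj > 1e-14, b / proj, np.inf)
        i = int(np.argmin(t))
        return t[i] * chat, i

    def facet_vertices(self, i: int) -> tuple[int, int]:
        """Indices (into ``vertices``) of the two endpoints of facet i."""
        simplex = self.hull.simplices[i]
        lookup = {v: j for j, v in enumerate(self.hull.vertices)}
        return lookup[simplex[0]], lookup[simplex[1]]


def build_elfving_set(
    space: DesignSpace,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    *,
    resolution: int = 400,
    forcing_window: str = "literal",
) -> ElfvingSet:
    """Sample f over the space, symmetrize, and take the 2-D convex hull."""
    if space.mode == "finite":
        pts = space.grid_points()
        dts = np.array([p.delta_t for p in pts])
        als = np.array([p.alpha for p in pts])
    else:
        if resolution < 2:
            raise ValueError("resolution must be >= 2")
        dts, als = space.sample(resolution, resolution)
    f = sensitivity_grid(dts, als, theta, k, forcing_window=forcing_window)
    pts2 = np.vstack([f, -f])
    gens = [(dt, a, +1) for dt, a in zip(dts, als)] + \
           [(dt, a, -1) for dt, a in zip(dts, als)]
    spread = pts2.max(0) - pts2.min(0)
    if np.min(spread) < 1e-12 * np.max(spread):
        raise ValueError("sensitivity curve degenerate (collinear images)")
    hull = ConvexHull(pts2)
    verts = pts2[hull.vertices]
    gen = tuple(gens[i] for i in hull.vertices)
    return ElfvingSet(verts, gen, hull, space.bounds)


def c_optimal_elfving(
    c,
    es: ElfvingSet,
    *,
    merge_tol: float = 1e-2,
) -> tuple[Design, float]:
    """c-optimal design from the Elfving geometry.

    The cut point c* on the hull boundary is written as a convex combination
    of the two endpoints of its facet; their generating maneuvers (signs
    dropped) with those coefficients form the design, and the criterion
    value is (|c| / |c*|)^2.  Generating maneuvers closer than ``merge_tol``
    in bounds-normalised coordinates (hull facets between neighbouring curve
    samples) merge into a one-point design.
    """
    c = np.asarray(c, float)
    cstar, facet = es.boundary_cut(c)
    j1, j2 = es.facet_vertices(facet)
    v1, v2 = es.vertices[j1], es.vertices[j2]
    edge = v2 - v1
    lam = float(np.clip(
        (cstar - v1) @ edge / (edge @ edge) if edge @ edge > 0 else 0.0,
        0.0, 1.0,
    ))  # cstar = (1-lam) v1 + lam v2
    phi = (np.linalg.norm(c) / np.linalg.norm(cstar)) ** 2
    (tl, th), (al, ah) = es.bounds
    scale = np.array([th - tl, ah - al])
    g1, g2 = es.generators[j1], es.generators[j2]
    z1, z2 = np.array(g1[:2]), np.array(g2[:2])
    if np.linalg.norm((z1 - z2) / scale) < merge_tol:
        z = (1 - lam) * z1 + lam * z2
        design = Design.from_arrays([z], [1.0])
        return design, float(phi)
    entries: dict[tuple[float, float], float] = {}
    for gen, wt in ((g1, 1 - lam), (g2, lam)):
        if wt < 1e-9:
            continue
        key = (gen[0], gen[1])
        entries[key] = entries.get(key, 0.0) + wt
    design = Design.from_arrays(list(entries), list(entries.values()))
    return design, float(phi)


def c_optimal_direct(
    c,
    space: DesignSpace,
    theta: ParameterVector = NOMINAL_THETA,
    k: PhysicalConstants = PhysicalConstants(),
    *,
    n_starts: int = 12,
    seed: int = _MULTISTART_SEED,
    forcing_window: str = "literal",
) -> tuple[Design, float]:
    """Independent cross-check: minimise c^T M^-(xi) c over <= 2-point
    designs by deterministic multistart nested optimisation."""
    c = np.asarray(c, float)
    if not np.any(c):
        raise ValueError("c must be nonzero")
    (tl, th), (al, ah) = space.bounds

    if space.mode == "finite":
        return _c_optimal_direct_finite(c, space, theta, k, forcing_window)

    def objective(x):
        z = np.clip(x[:4], [tl, al, tl, al], [th, ah, th, ah])
        w = 1.0 / (1.0 + math.exp(-float(np.clip(x[4], -30, 30))))
        f = sensitivity_grid([z[0], z[2]], [z[1], z[3]], theta, k,
                             forcing_window=forcing_window)
        m = w * np.outer(f[0], f[0]) + (1 - w) * np.outer(f[1], f[1])
        return _phi_c_ginv(m, c)

    rng = np.random.default_rng(seed)
    best, best_val = None, np.inf
    for _ in range(n_starts):
        x0 = np.concatenate([
            rng.uniform([tl, al, tl, al], [th, ah, th, ah]),
            rng.normal(size=1),
        ])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12,
                                "maxiter": 4000})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None or not np.isfinite(best_val):  # pragma: no cover
        raise RuntimeError("direct c-optimization failed from all starts")
    z = np.clip(best[:4], [tl, al, tl, al], [th, ah, th, ah])
    w = 1.0 / (1.0 + math.exp(-float(np.clip(best[4], -30, 30))))
    pts = [(z[0], z[1]), (z[2], z[3])]
    weights = [w, 1 - w]
    # collapse to a one-point design when a weight or the separation dies
    if w < 1e-6 or np.hypot(*(np.subtract(pts[0], pts[1]))) < 1e-9:
        pts, weights = [pts[1]], [1.0]
    elif 1 - w < 1e-6:
        pts, weights = [pts[0]], [1.0]
    return Design.from_arrays(pts, weights), float(best_val)


def _phi_c_ginv(m, c):
    """c^T M^- c with an estimability (range) check."""
    minv = np.linalg.pinv(m, rcond=1e-12)
    resid = c - m @ (minv @ c)
    if np.linalg.norm(resid) > 1e-7 * np.linalg.norm(c):
        return np.inf
    return float(c @ minv @ c)


def _c_optimal_direct_finite(c, space, theta, k, forcing_window):
    """Exhaustive search over grid pairs with an inner 1-D weight solve."""
    pts = space.grid_points()
    f = sensitivity_grid([p.delta_t for p in pts], [p.alpha for p in pts],
                         theta, k, forcing_window=forcing_window)
    best, best_val = None, np.inf
    n = len(pts)
    for i in range(n):
        val = _phi_c_ginv(np.outer(f[i], f[i]), c)
        if val < best_val:
            best, best_val = ([pts[i]], [1.0]), val
        for j in range(i + 1, n):
            for w in _golden_weight(f[i], f[j], c):
                m = w * np.outer(f[i], f[i]) + (1 - w) * np.outer(f[j], f[j])
                val = _phi_c_ginv(m, c)
                if val < best_val:
                    best, best_val = ([pts[i], pts[j]], [w, 1 - w]), val
    pts_b, w_b = best
    keep = [(p, w) for p, w in zip(pts_b, w_b) if w > 1e-9]
    return Design.from_arrays([p for p, _ in keep],
                              [w for _, w in keep]), float(best_val)


def _golden_weight(f1, f2, c, tol=1e-10):
    """Minimise the 1-D weight for a fixed support pair (golden section)."""
    def phi(w):
        m = w * np.outer(f1, f1) + (1 - w) * np.outer(f2, f2)
        return _phi_c_ginv(m, c)

    lo, hi = 1e-9, 1 - 1e-9
    invphi = (math.sqrt(5) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1v, f2v = phi(x1), phi(x2)
    while hi - lo > tol:
        if f1v < f2v:
            hi, x2, f2v = x2, x1, f1v
            x1 = hi - invphi * (hi - lo)
            f1v = phi(x1)
        else:
            lo, x1, f1v = x1, x2, f2v
            x2 = lo + invphi * (hi - lo)
            f2v = phi(x2)
    yield 0.5 * (lo + hi)
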