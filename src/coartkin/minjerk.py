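"""Minimum-jerk submovement superposition and the overlap sweep.

The validation model for the coarticulation score: a trial is the
superposition of four straight minimum-jerk strokes chained
A -> B' -> C -> D' -> A.  Each stroke follows the quintic displacement
profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 (zero velocity and
acceleration at both ends, peak speed 15/8 * D/T at midstroke).
"Overlap" o means the next stroke starts o*T before the previous one
ends; it is applied to the (1,2) and (3,4) pairs, while the (2,3) pair
stays strictly sequential because the task forces a near stop at C.

Because overlapping strokes 1 and 2 pulls the blended path inside
target B (and likewise 3, 4 inside D), the virtual via-points B', D'
are found by non-linear optimization so the superposed path still
passes through the physical targets.  Sweeping o from 0 to 0.55 maps
overlap to the predicted coarticulation score and path offset; the
monotone score curve can then be inverted to estimate a trial's overlap
from its measured score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .errors import OptimizationError
from .layout import TargetLayout
from .measures import (
    boundary_times as _boundary_times_measures,
    coarticulation_score,
    count_velocity_peaks,
    find_peak_structure,
    path_offset_xy,
)
from .preprocess import VelocityProfile

__all__ = [
    "Submovement",
    "SimTrajectory",
    "SimulationCurve",
    "minjerk_pos",
    "minjerk_vel",
    "minjerk_segment",
    "chain_submovements",
    "superpose",
    "solve_via_points",
    "simulate_grid",
    "estimate_overlap",
    "grid_profile",
]

MAX_OVERLAP = 0.55


def minjerk_pos(tau):
    """Normalized minimum-jerk displacement 10 tau^3 - 15 tau^4 + 6 tau^5."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minjerk_vel(tau):
    """d/dtau of the displacement profile: 30 tau^2 - 60 tau^3 + 30 tau^4."""
    tau = np.asarray(tau, float)
    out = 30.0 * tau**2 * (1.0 - tau) ** 2
    return np.where((tau < 0.0) | (tau > 1.0), 0.0, out)


@dataclass
class Submovement:
    """One straight minimum-jerk stroke."""

    start: np.ndarray
    end: np.ndarray
    onset: float
    duration: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, float)
        self.end = np.asarray(self.end, float)
        if self.duration <= 0:
            raise ValueError("submovement duration must be positive")

    @property
    def displacement(self) -> np.ndarray:
        return self.end - self.start

    def pos_contrib(self, t) -> np.ndarray:
        """(n,2) displacement contribution at times t (0 before onset)."""
        tau = (np.asarray(t, float) - self.onset) / self.duration
        return np.outer(minjerk_pos(tau), self.displacement)

    def vel_contrib(self, t) -> np.ndarray:
        tau = (np.asarray(t, float) - self.onset) / self.duration
        return np.outer(minjerk_vel(tau) / self.duration, self.displacement)


@dataclass
class SimTrajectory:
    """A simulated trial: sampled positions and analytic velocities."""

    t: np.ndarray
    xy: np.ndarray
    vxy: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vxy[:, 0], self.vxy[:, 1])

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]


def minjerk_segment(sub: Submovement, dt: float) -> SimTrajectory:
    """Sample a single stroke on its own [onset, onset+T] support."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(sub.duration / dt))
    t = sub.onset + np.arange(n + 1) * dt
    return SimTrajectory(
        t=t, xy=sub.start + sub.pos_contrib(t), vxy=sub.vel_contrib(t)
    )


def chain_submovements(
    waypoints: np.ndarray, overlap: float, t_sub: float
) -> list[Submovement]:
    """Four chained strokes with overlap on the (1,2) and (3,4) pairs.

    Onsets: the second (fourth) stroke starts overlap*t_sub before the
    first (third) ends; stroke 3 starts exactly when stroke 2 ends.
    """
    if not 0.0 <= overlap <= MAX_OVERLAP:
        raise ValueError(f"overlap must be in [0, {MAX_OVERLAP}], got {overlap}")
    w = np.asarray(waypoints, float)
    if w.shape != (5, 2):
        raise ValueError("need 5 waypoints (A, B', C, D', A)")
    T = t_sub
    onsets = [0.0, (1 - overlap) * T, (2 - overlap) * T, (3 - 2 * overlap) * T]
    return [
        Submovement(start=w[k], end=w[k + 1], onset=onsets[k], duration=T)
        for k in range(4)
    ]


def _eval(subs: list[Submovement], t) -> tuple[np.ndarray, np.ndarray]:
    origin = subs[0].start
    pos = origin + sum(s.pos_contrib(t) for s in subs)
    vel = sum(s.vel_contrib(t) for s in subs)
    return pos, vel


def superpose(subs: list[Submovement], dt: float) -> SimTrajectory:
    """Vector-sum the strokes on a uniform grid covering their support.

    Positions telescope: the trajectory ends exactly at the last
    stroke's endpoint (A for the closed task) for every overlap.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_end = max(s.onset + s.duration for s in subs)
    n = int(np.ceil(t_end / dt - 1e-9))
    t = np.arange(n + 1) * dt
    if t[-1] < t_end:
        t = np.append(t, t_end)
    pos, vel = _eval(subs, t)
    return SimTrajectory(t=t, xy=pos, vxy=vel)


def _closest_approach(
    subs: list[Submovement], point: np.ndarray, tspan: tuple[float, float], dt: float
) -> float:
    """Minimum distance of the superposed path to a point over tspan.

    Coarse grid scan refined by bounded scalar minimization on the
    analytic path, so the result is not limited by the sampling step.
    """
    t0, t1 = tspan
    t = np.linspace(t0, t1, max(int((t1 - t0) / dt), 8) + 1)
    pos, _ = _eval(subs, t)
    d = np.hypot(*(pos - point).T)
    i = int(np.argmin(d))
    lo, hi = t[max(i - 1, 0)], t[min(i + 1, len(t) - 1)]

    def f(tt):
        p, _ = _eval(subs, np.array([tt]))
        return float(np.hypot(*(p[0] - point)))

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    return min(float(d[i]), float(res.fun))


def _fast_min_dist(
    subs: list[Submovement], point: np.ndarray, tspan: tuple[float, float], dt: float
) -> float:
    """Cheap closest-approach for inner optimization loops.

    Grid scan plus one parabolic refinement of the squared distance
    around the grid minimum (the squared distance is locally quadratic
    in time, so this is accurate to well below the solver tolerance).
    """
    t0, t1 = tspan
    t = np.linspace(t0, t1, max(int((t1 - t0) / dt), 8) + 1)
    pos, _ = _eval(subs, t)
    d2 = np.sum((pos - point) ** 2, axis=1)
    i = int(np.argmin(d2))
    best = d2[i]
    if 0 < i < len(t) - 1:
        a, b, c = d2[i - 1], d2[i], d2[i + 1]
        denom = a - 2 * b + c
        if denom > 0:
            shift = 0.5 * (a - c) / denom
            tt = t[i] + shift * (t[1] - t[0])
            p, _ = _eval(subs, np.array([tt]))
            best = min(best, float(np.sum((p[0] - point) ** 2)))
    return float(np.sqrt(best))


@dataclass
class ViaSolution:
    """Optimized virtual via-points and the achieved miss distances (cm)."""

    b_prime: np.ndarray
    d_prime: np.ndarray
    residual_b_cm: float
    residual_d_cm: float


def solve_via_points(
    layout: TargetLayout,
    overlap: float,
    t_sub: float = 0.5,
    dt: float = 1.0 / 160.0,
    tol_cm: float = 1e-3,
    max_restarts: int = 5,
    seed: int = 0,
    x0: tuple[np.ndarray, np.ndarray] | None = None,
) -> ViaSolution:
    """Find B', D' so the superposed path passes through B and D.

    The two problems are separable: B must be crossed while strokes 1-2
    are active and D while strokes 3-4 are.  Blending pulls the path to
    the inside of each corner, and the through-the-target condition
    alone leaves a one-parameter family of via-points, so each
    via-point is sought on the ray from the physical target along the
    corner's outward angle bisector: a bounded derivative-free scalar
    minimization of the squared closest approach (coarse scan plus
    Brent refinement).  This is deterministic, unique, and smooth in
    the overlap.  If the ray search cannot reach ``tol_cm`` the solver
    falls back to an unrestricted 2-D Nelder-Mead search with up to
    ``max_restarts`` jittered restarts (seeded RNG) before raising.
    """
    A, B, C, D = (layout.center(lbl) for lbl in "ABCD")
    if overlap == 0.0:
        return ViaSolution(B.copy(), D.copy(), 0.0, 0.0)

    T = t_sub

    def _unit(v):
        return v / np.hypot(*v)

    def solve_ray(target, span, u, other_fixed, first_pair, s_warm):
        def waypoints(p):
            if first_pair:
                return np.stack([A, p, C, other_fixed, A])
            return np.stack([A, other_fixed, C, p, A])

        def miss(s):
            subs = chain_submovements(waypoints(target + s * u), overlap, T)
            return _fast_min_dist(subs, target, span, dt)

        # bracket the minimum: warm-started narrow scan, else full range
        for lo, hi, m in (
            (max(0.0, s_warm - 0.4), s_warm + 0.4, 17),
            (0.0, 6.0, 49),
        ):
            grid = np.linspace(lo, hi, m)
            vals = np.array([miss(s) for s in grid])
            i = int(np.argmin(vals))
            if 0 < i < m - 1 or (lo == 0.0 and i == 0):
                blo = grid[max(i - 1, 0)]
                bhi = grid[min(i + 1, m - 1)]
                res = minimize_scalar(
                    miss, bounds=(blo, bhi), method="bounded",
                    options={"xatol": 1e-8},
                )
                s_best = float(res.x) if res.fun < vals[i] else float(grid[i])
                p = target + s_best * u
                subs = chain_submovements(waypoints(p), overlap, T)
                resid = _closest_approach(subs, target, span, dt)
                if resid <= tol_cm:
                    return p, resid, s_best
        return None

    def solve_free(target, span, start, other_fixed, first_pair):
        rng = np.random.default_rng(seed)

        def objective(p):
            if first_pair:
                w = np.stack([A, p, C, other_fixed, A])
            else:
                w = np.stack([A, other_fixed, C, p, A])
            return _fast_min_dist(
                chain_submovements(w, overlap, T), target, span, dt
            ) ** 2

        guess = np.asarray(start, float)
        best_p, best_f = guess, np.inf
        for attempt in range(max_restarts + 1):
            p0 = guess if attempt == 0 else guess + rng.normal(0.0, 0.3, 2)
            res = minimize(
                objective, p0, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 400},
            )
            if res.fun < best_f:
                best_p, best_f = np.asarray(res.x), float(res.fun)
            if best_f <= (0.5 * tol_cm) ** 2:
                break
        resid = _closest_approach(
            chain_submovements(
                np.stack([A, best_p, C, other_fixed, A])
                if first_pair
                else np.stack([A, other_fixed, C, best_p, A]),
                overlap,
                T,
            ),
            target,
            span,
            dt,
        )
        if resid > tol_cm:
            raise OptimizationError(
                f"via-point solve failed at overlap={overlap:.4f}: residual "
                f"{resid:.2e} cm > {tol_cm:.0e} cm after {max_restarts} restarts"
            )
        return best_p, resid

    # outward angle bisectors at the two blended corners
    u_b = _unit(_unit(B - A) + _unit(B - C))
    u_d = _unit(_unit(D - C) + _unit(D - A))
    span_b = (0.0, (2 - overlap) * T)
    span_d = ((2 - overlap) * T, (4 - 2 * overlap) * T)

    def warm_s(x0_point, target, u):
        return max(0.0, float((np.asarray(x0_point) - target) @ u))

    s_b = warm_s(x0[0], B, u_b) if x0 is not None else 0.0
    s_d = warm_s(x0[1], D, u_d) if x0 is not None else 0.0

    got = solve_ray(B, span_b, u_b, D, True, s_b)
    if got is not None:
        b_prime, rb, _ = got
    else:
        b_prime, rb = solve_free(B, span_b, B if x0 is None else x0[0], D, True)
    got = solve_ray(D, span_d, u_d, b_prime, False, s_d)
    if got is not None:
        d_prime, rd, _ = got
    else:
        d_prime, rd = solve_free(
            D, span_d, D if x0 is None else x0[1], b_prime, False
        )
    return ViaSolution(b_prime, d_prime, rb, rd)


@dataclass
class SimulationCurve:
    """Overlap grid with predicted score, curvature, and peak count."""

    overlap: np.ndarray
    score: np.ndarray
    curvature_cm: np.ndarray
    n_peaks: np.ndarray
    residual_b_cm: np.ndarray
    residual_d_cm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap": self.overlap,
                "score": self.score,
                "curvature_cm": self.curvature_cm,
                "n_peaks": self.n_peaks,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimulationCurve":
        z = np.zeros(len(df))
        return cls(
            overlap=df["overlap"].to_numpy(float),
            score=df["score"].to_numpy(float),
            curvature_cm=df["curvature_cm"].to_numpy(float),
            n_peaks=df["n_peaks"].to_numpy(int),
            residual_b_cm=z,
            residual_d_cm=z.copy(),
        )


def _sim_boundary_times(traj: SimTrajectory, layout: TargetLayout) -> np.ndarray:
    out = []
    for lbl in ("B", "C", "D"):
        d = np.hypot(*(traj.xy - layout.center(lbl)).T)
        out.append(traj.t[int(np.argmin(d))])
    return np.array(out)


def grid_profile(
    layout: TargetLayout,
    overlap: float,
    via: ViaSolution,
    t_sub: float = 0.5,
    dt: float = 1.0 / 160.0,
    oversample: int = 8,
) -> tuple[SimTrajectory, float, float, int]:
    """Superpose one grid point and measure it: (traj, score, offset, peaks).

    The analytic profile is sampled at ``dt / oversample`` for
    measurement: at the recording rate itself, extremum heights are
    quantized by the sample grid, which puts visible stair-step jitter
    on the otherwise smooth score and curvature curves.
    """
    A, C = layout.center("A"), layout.center("C")
    w = np.stack([A, via.b_prime, C, via.d_prime, A])
    traj = superpose(chain_submovements(w, overlap, t_sub), dt / max(oversample, 1))
    vp = VelocityProfile(traj.t, traj.speed)
    bt = _sim_boundary_times(traj, layout)
    ps = find_peak_structure(vp, boundary_times=bt)
    score = coarticulation_score(ps)
    offset = path_offset_xy(traj.xy, layout)
    n_pk = count_velocity_peaks(vp)
    return traj, score, offset, n_pk


def simulate_grid(
    layout: TargetLayout,
    o_min: float = 0.0,
    o_max: float = MAX_OVERLAP,
    n: int = 551,
    t_sub: float = 0.5,
    dt: float = 1.0 / 160.0,
    seed: int = 0,
) -> SimulationCurve:
    """The overlap sweep: n equally spaced overlaps from o_min to o_max.

    Each point solves the via-point problem (warm-started from the
    previous overlap), superposes the strokes, and runs the measure
    pipeline.  The returned score curve starts at 0 and increases with
    overlap; the peak count drops from 4 as the blends merge.
    """
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    grid = np.linspace(o_min, o_max, n)
    score = np.empty(n)
    curv = np.empty(n)
    n_pk = np.empty(n, dtype=int)
    res_b = np.empty(n)
    res_d = np.empty(n)
    warm = None
    for i, o in enumerate(grid):
        via = solve_via_points(
            layout, float(o), t_sub=t_sub, dt=dt, seed=seed, x0=warm
        )
        warm = (via.b_prime, via.d_prime)
        _, score[i], curv[i], n_pk[i] = grid_profile(layout, float(o), via, t_sub, dt)
        res_b[i], res_d[i] = via.residual_b_cm, via.residual_d_cm
    return SimulationCurve(grid, score, curv, n_pk, res_b, res_d)


def estimate_overlap(curve: SimulationCurve, observed_score: float) -> float:
    """Invert the score curve: observed score -> overlap fraction.

    Monotone interpolation on the grid; scores outside the curve's
    range are clamped to the nearest endpoint with a warning.
    """
    import warnings

    s = np.maximum.accumulate(curve.score)  # guard tiny numeric dips
    if observed_score <= s[0]:
        if observed_score < s[0]:
            warnings.warn("observed score below simulated range; clamping")
        return float(curve.overlap[0])
    if observed_score >= s[-1]:
        if observed_score > s[-1]:
            warnings.warn("observed score above simulated range; clamping")
        return float(curve.overlap[-1])
    return float(np.interp(observed_score, s, curve.overlap))
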