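"""Steady states, stability classification, and (AUT-A, APO-A) balance curves.

Equilibria of the full five-variable system are found by multi-start Newton
root finding (a regular 3-per-axis grid over the (aut_a, apo_a, bcl2) box plus
seeded random starts), merged at a max-norm tolerance and classified by the
eigenvalues of the analytic Jacobian.

The balance curves ("nullclines") live in the (AUT-A, APO-A) plane: the three
remaining states (upr, bcl2, aut_i) are put at their quasi-steady state given
the plane coordinates, and the locus where the plane variable's production
exactly balances its consumption is traced as a polyline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from erswitch.model import (
    STATE_NAMES,
    ModelState,
    ParameterSet,
    StressorInput,
    _jac_raw,
    _rhs_raw,
)

__all__ = [
    "Equilibrium",
    "NullclineCurve",
    "classify_stability",
    "find_equilibria",
    "nullclines",
    "nullcline_intersections",
    "qss_reduce",
]

STABILITY_EPS = 1e-9
MERGE_TOL = 1e-6
RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class Equilibrium:
    state: ModelState
    eigenvalues: np.ndarray
    stability: str  # stable | saddle | unstable | marginal

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class NullclineCurve:
    """Balance curve of one plane variable, as ordered polyline branches."""

    variable: str  # "aut_a" or "apo_a"
    branches: list[np.ndarray]  # each (m, 2) array of (aut_a, apo_a) points
    input: StressorInput

    @property
    def points(self) -> np.ndarray:
        if not self.branches:
            return np.empty((0, 2))
        return np.vstack(self.branches)


def classify_stability(eigenvalues, eps: float = STABILITY_EPS) -> str:
    """Classify a 5-tuple of Jacobian eigenvalues by their real parts."""
    re = np.real(np.asarray(eigenvalues, dtype=complex))
    if len(re) != 5:
        raise ValueError("expected 5 eigenvalues")
    if np.any(np.abs(re) <= eps):
        return "marginal"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def _solve_from(y0, p: ParameterSet, u: tuple) -> np.ndarray | None:
    sol = root(
        lambda y: _rhs_raw(y, p, *u),
        y0,
        jac=lambda y: _jac_raw(y, p, *u),
        method="hybr",
        tol=1e-12,
    )
    if not sol.success:
        return None
    y = sol.x
    # polish with plain Newton to push the residual below RESIDUAL_TOL
    for _ in range(5):
        r = _rhs_raw(y, p, *u)
        if np.max(np.abs(r)) < RESIDUAL_TOL:
            break
        try:
            y = y - np.linalg.solve(_jac_raw(y, p, *u), r)
        except np.linalg.LinAlgError:
            return None
    if np.max(np.abs(_rhs_raw(y, p, *u))) >= RESIDUAL_TOL:
        return None
    return y


def _relax(y0, p: ParameterSet, u: tuple, t_relax: float = 30.0) -> np.ndarray:
    from scipy.integrate import solve_ivp

    sol = solve_ivp(lambda t, y: _rhs_raw(y, p, *u), (0.0, t_relax), y0,
                    method="LSODA", jac=lambda t, y: _jac_raw(y, p, *u),
                    rtol=1e-8, atol=1e-10)
    return sol.y[:, -1] if sol.success else y0


def _in_box(y, p: ParameterSet, tol: float = 1e-8) -> bool:
    u, b, a, i, q = y
    return (
        -tol <= u <= p.upr_t + tol
        and -tol <= b <= p.bcl2_t + tol
        and a >= -tol
        and i >= -tol
        and a + i <= p.aut_t + tol
        and -tol <= q <= p.apo_t + tol
    )


def find_equilibria(params: ParameterSet, inp: StressorInput,
                    n_starts: int = 60, seed: int = 0,
                    merge_tol: float = MERGE_TOL) -> list[Equilibrium]:
    """All steady states in the admissible box, sorted by apo_a ascending.

    Starts are a regular 3-per-axis grid over (aut_a, apo_a, bcl2) with the
    fast variables (upr, aut_i) at quasi-steady state, plus seeded random
    starts filling up to ``n_starts``.  Converged roots are merged at
    max-norm tolerance, refined to residual < 1e-10 and classified via the
    Jacobian eigenvalues.
    """
    if n_starts < 27:
        raise ValueError("n_starts must be >= 27 (3-per-axis grid)")
    params.validate()
    inp.validate()
    u = (inp.stress, inp.tg, inp.dtt, inp.kaua_mult)

    act_u = params.ks_upr + params.kact_upr * inp.stress
    upr_qss = act_u * params.upr_t / (act_u + params.kin_upr + params.kd_upr)

    grid = [0.05, 0.5, 0.95]
    starts = []
    for fa, fq, fb in itertools.product(grid, grid, grid):
        a = fa * params.aut_t
        q = fq * params.apo_t
        i = (params.cleave_rate * q * a / params.kd_auti
             if params.kd_auti > 0 else 0.0)
        i = min(i, max(params.aut_t - a, 0.0))
        starts.append([upr_qss, fb * params.bcl2_t, a, i, q])
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        a = rng.uniform(0, params.aut_t)
        i = rng.uniform(0, params.aut_t - a)
        starts.append([
            rng.uniform(0, params.upr_t),
            rng.uniform(0, params.bcl2_t),
            a,
            i,
            rng.uniform(0, params.apo_t),
        ])

    # sharp (small-J) kinetics give stable states tiny Newton basins: raw
    # Newton from the grid reliably finds saddles but can miss attractors,
    # so the corner starts are additionally relaxed along the flow first
    corner = [0.05, 0.95]
    for fa, fq, fb in itertools.product(corner, corner, corner):
        a = fa * params.aut_t
        q = fq * params.apo_t
        y0 = np.array([upr_qss, fb * params.bcl2_t, a,
                       min(0.05, params.aut_t - a), q])
        starts.append(_relax(y0, params, u))

    roots: list[np.ndarray] = []
    any_converged = False
    for y0 in starts:
        y = _solve_from(np.asarray(y0, dtype=float), params, u)
        if y is None:
            continue
        any_converged = True
        if not _in_box(y, params):
            continue
        if all(np.max(np.abs(y - r)) > merge_tol for r in roots):
            roots.append(y)

    if not roots:
        warnings.warn(
            "find_equilibria: no converged root in the admissible box"
            + ("" if any_converged else " (no start converged at all)"),
            RuntimeWarning,
        )
        return []

    out = []
    for y in sorted(roots, key=lambda r: r[4]):
        ev = np.linalg.eigvals(_jac_raw(y, params, *u))
        out.append(Equilibrium(state=ModelState.from_array(y),
                               eigenvalues=ev,
                               stability=classify_stability(ev)))
    return out


# --------------------------------------------------------------------------
# quasi-steady-state reduction and nullclines


def qss_reduce(aut_a: float, apo_a: float, params: ParameterSet,
               inp: StressorInput,
               y0: np.ndarray | None = None) -> np.ndarray | None:
    """Solve (upr, bcl2, aut_i) to steady state given the plane coordinates.

    Root finding on the 3-variable subsystem (not analytic elimination), so
    the reduction stays valid for any kinetic form of the hidden states.
    Returns the full 5-vector or ``None`` if the solve fails.
    """
    u_in = (inp.stress, inp.tg, inp.dtt, inp.kaua_mult)
    idx = [0, 1, 3]  # upr, bcl2, aut_i

    def sub(z):
        y = np.array([z[0], z[1], aut_a, z[2], apo_a])
        return _rhs_raw(y, params, *u_in)[idx]

    def sub_jac(z):
        y = np.array([z[0], z[1], aut_a, z[2], apo_a])
        return _jac_raw(y, params, *u_in)[np.ix_(idx, idx)]

    act_u = params.ks_upr + params.kact_upr * inp.stress
    upr0 = act_u * params.upr_t / (act_u + params.kin_upr + params.kd_upr)
    i0 = (params.cleave_rate * apo_a * aut_a / params.kd_auti
          if params.kd_auti > 0 else 0.0)
    i0 = min(i0, params.aut_t)
    starts = []
    if y0 is not None:
        starts.append(np.asarray(y0, dtype=float)[idx])
    starts += [np.array([upr0, f * params.bcl2_t, i0])
               for f in (0.5, 0.95, 0.05)]
    def physical(z) -> bool:
        # the kinetic terms have spurious roots outside the box (MM poles);
        # only solutions inside it are meaningful
        return (-1e-9 <= z[0] <= params.upr_t + 1e-9
                and -1e-9 <= z[1] <= params.bcl2_t + 1e-9
                and -1e-9 <= z[2] <= params.aut_t + 1e-9)

    for z0 in starts:
        sol = root(sub, z0, jac=sub_jac, method="hybr", tol=1e-12)
        if (sol.success and np.max(np.abs(sub(sol.x))) < 1e-9
                and physical(sol.x)):
            return np.array([sol.x[0], sol.x[1], aut_a, sol.x[2], apo_a])

    # fallback: sequential scalar bracketing.  The upr and aut_i balances do
    # not involve bcl2, and each residual is strictly monotone in its own
    # variable, so brentq on the rhs components is guaranteed to converge.
    from scipy.optimize import brentq

    def comp(k, z):
        y = np.array([z[0], z[1], aut_a, z[2], apo_a])
        return _rhs_raw(y, params, *u_in)[k]

    try:
        z = np.array([upr0, 0.5 * params.bcl2_t, i0])
        z[0] = brentq(lambda v: comp(0, [v, z[1], z[2]]),
                      0.0, params.upr_t, xtol=1e-14)
        hi = max(params.aut_t, i0 + 1.0)
        z[2] = brentq(lambda v: comp(3, [z[0], z[1], v]), 0.0, hi, xtol=1e-14)
        z[1] = brentq(lambda v: comp(1, [z[0], v, z[2]]),
                      0.0, params.bcl2_t, xtol=1e-14)
    except ValueError:
        return None
    if np.max(np.abs(sub(z))) > 1e-9:
        return None
    return np.array([z[0], z[1], aut_a, z[2], apo_a])


def _qss_rate(aut_a, apo_a, params, inp, which: int,
              y0=None) -> tuple[float, np.ndarray] | None:
    y = qss_reduce(aut_a, apo_a, params, inp, y0=y0)
    if y is None:
        return None
    r = _rhs_raw(y, params, inp.stress, inp.tg, inp.dtt, inp.kaua_mult)
    return float(r[which]), y


def nullclines(params: ParameterSet, inp: StressorInput,
               resolution: int = 120) -> tuple[NullclineCurve, NullclineCurve]:
    """Balance curves of AUT-A and APO-A in the (aut_a, apo_a) plane.

    The plane rate of each variable is evaluated on a resolution x resolution
    grid (hidden states at quasi-steady state per grid point); zero contours
    are extracted with contourpy and every vertex is refined by bisection
    along a grid direction to residual < 1e-6.
    """
    if resolution < 100:
        raise ValueError("resolution must be >= 100")
    params.validate()
    inp.validate()
    from contourpy import contour_generator

    a_grid = np.linspace(1e-6, params.aut_t * (1 - 1e-6), resolution)
    q_grid = np.linspace(1e-6, params.apo_t * (1 - 1e-6), resolution)
    rates = {2: np.full((resolution, resolution), np.nan),
             4: np.full((resolution, resolution), np.nan)}
    skipped = 0
    for jq, q in enumerate(q_grid):
        for ja, a in enumerate(a_grid):
            y = qss_reduce(a, q, params, inp)
            if y is None:
                skipped += 1
                continue
            r = _rhs_raw(y, params, inp.stress, inp.tg, inp.dtt, inp.kaua_mult)
            rates[2][jq, ja] = r[2]
            rates[4][jq, ja] = r[4]
    total = resolution * resolution
    if skipped > 0.2 * total:
        raise RuntimeError(
            f"QSS reduction failed at {skipped}/{total} grid points"
        )
    if skipped:
        warnings.warn(f"QSS reduction skipped {skipped} grid points",
                      RuntimeWarning)

    curves = []
    for which, name in ((2, "aut_a"), (4, "apo_a")):
        gen = contour_generator(x=a_grid, y=q_grid, z=rates[which])
        branches = []
        for poly in gen.lines(0.0):
            pts = np.asarray(poly, dtype=float)
            refined = np.array([
                _refine_nullcline_point(pt, params, inp, which, a_grid, q_grid)
                for pt in pts
            ])
            branches.append(refined)
        curves.append(NullclineCurve(variable=name, branches=branches,
                                     input=inp))
    return curves[0], curves[1]


def _refine_nullcline_point(pt, params, inp, which, a_grid, q_grid,
                            tol: float = 1e-8):
    """Polish one contour vertex by a 1-d bisection along a grid axis."""
    a, q = float(pt[0]), float(pt[1])
    h_a = a_grid[1] - a_grid[0]
    h_q = q_grid[1] - q_grid[0]

    def rate(a_, q_):
        out = _qss_rate(a_, q_, params, inp, which)
        return None if out is None else out[0]

    r0 = rate(a, q)
    if r0 is None:
        return np.array([a, q])
    if abs(r0) < tol:
        return np.array([a, q])
    # try bracketing along each axis over one grid spacing
    for axis, h in ((1, h_q), (0, h_a)):
        for sign in (+1.0, -1.0):
            if axis == 1:
                a1, q1 = a, min(max(q + sign * h, q_grid[0]), q_grid[-1])
            else:
                a1, q1 = min(max(a + sign * h, a_grid[0]), a_grid[-1]), q
            r1 = rate(a1, q1)
            if r1 is None or r0 * r1 > 0:
                continue
            lo, hi = (a, q), (a1, q1)
            rlo = r0
            for _ in range(60):
                mid = (0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1]))
                rm = rate(*mid)
                if rm is None:
                    break
                if abs(rm) < tol:
                    return np.array(mid)
                if rlo * rm <= 0:
                    hi = mid
                else:
                    lo, rlo = mid, rm
            return np.array([0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1])])
    return np.array([a, q])


def _segment_intersections(p1, p2, p3, p4):
    """Intersection point of segments p1-p2 and p3-p4, or None."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-14:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / denom
    s = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= s <= 1.0:
        return p1 + t * d1
    return None


def nullcline_intersections(curve_a: NullclineCurve,
                            curve_q: NullclineCurve) -> np.ndarray:
    """Crossings of the two balance curves (candidate equilibria), by
    segment-pair intersection detection; duplicates merged at 1e-6."""
    pts = []
    for br_a in curve_a.branches:
        for br_q in curve_q.branches:
            for i in range(len(br_a) - 1):
                for j in range(len(br_q) - 1):
                    x = _segment_intersections(br_a[i], br_a[i + 1],
                                               br_q[j], br_q[j + 1])
                    if x is not None:
                        pts.append(x)
    merged: list[np.ndarray] = []
    for x in pts:
        if all(np.max(np.abs(x - m)) > 1e-6 for m in merged):
            merged.append(x)
    merged.sort(key=lambda x: x[1])
    return np.array(merged) if merged else np.empty((0, 2))
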