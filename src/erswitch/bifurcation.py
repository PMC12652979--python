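"""One-parameter bifurcation diagrams in the ER stress level.

Equilibrium branches are traced by pseudo-arclength continuation (secant
predictor, Newton corrector on the bordered system, adaptive steps); folds
(saddle-node / limit points) are detected as sign changes of the stress
progression along arclength and refined by bisection.  A dense-sweep fallback
(multi-start root finding on a fine stress grid, nearest-neighbour linking)
serves as an independent oracle for the continuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from erswitch.model import ModelState, ParameterSet, StressorInput, _jac_raw, _rhs_raw
from erswitch.equilibria import classify_stability, find_equilibria

__all__ = [
    "BranchPoint",
    "BifurcationDiagram",
    "continue_in_stress",
    "bistable_interval",
    "dense_sweep",
]

RESIDUAL_TOL = 1e-8
FOLD_TOL = 1e-4


@dataclass(frozen=True)
class BranchPoint:
    stress: float
    state: ModelState
    stability: str
    eigenvalues: np.ndarray


@dataclass
class BifurcationDiagram:
    """Branches of equilibria over a stress range, with fold annotations."""

    branches: list[list[BranchPoint]]
    limit_points: list[float]
    stress_range: tuple[float, float]
    log: list[str] = field(default_factory=list)

    @property
    def bistable_interval(self) -> tuple[float, float] | None:
        return bistable_interval(self)

    def to_frame(self):
        import pandas as pd

        rows = []
        for bid, branch in enumerate(self.branches):
            for pt in branch:
                s = pt.state
                rows.append({
                    "stress": pt.stress, "upr": s.upr, "bcl2": s.bcl2,
                    "aut_a": s.aut_a, "aut_i": s.aut_i, "apo_a": s.apo_a,
                    "stability": pt.stability, "branch": bid,
                })
        return pd.DataFrame(rows)


def _drhs_dstress(y, p: ParameterSet) -> np.ndarray:
    """Partial derivative of the RHS with respect to the stress input.

    Stress enters only the UPR activation term."""
    out = np.zeros(5)
    out[0] = p.kact_upr * (p.upr_t - y[0])
    return out


def _corrector(x, x_pred, tangent, p: ParameterSet, tmpl: StressorInput,
               max_iter: int = 12, tol: float = 1e-11):
    """Newton solve of [rhs(y; s) = 0, tangent . (x - x_pred) = 0]."""
    x = x.copy()
    for _ in range(max_iter):
        y, s = x[:5], x[5]
        u = (s, tmpl.tg, tmpl.dtt, tmpl.kaua_mult)
        r = _rhs_raw(y, p, *u)
        g = float(tangent @ (x - x_pred))
        if np.max(np.abs(r)) < tol and abs(g) < tol:
            return x
        A = np.zeros((6, 6))
        A[:5, :5] = _jac_raw(y, p, *u)
        A[:5, 5] = _drhs_dstress(y, p)
        A[5, :] = tangent
        try:
            dx = np.linalg.solve(A, np.concatenate([r, [g]]))
        except np.linalg.LinAlgError:
            return None
        x = x - dx
        if not np.all(np.isfinite(x)):
            return None
    return None


def _solve_at_stress(y0, s, p: ParameterSet, tmpl: StressorInput):
    """Newton refine an equilibrium at fixed stress."""
    u = (s, tmpl.tg, tmpl.dtt, tmpl.kaua_mult)
    y = np.asarray(y0, dtype=float).copy()
    for _ in range(30):
        r = _rhs_raw(y, p, *u)
        if np.max(np.abs(r)) < 1e-12:
            return y
        try:
            y = y - np.linalg.solve(_jac_raw(y, p, *u), r)
        except np.linalg.LinAlgError:
            return None
    return y if np.max(np.abs(_rhs_raw(y, p, *u))) < 1e-10 else None


def _branch_point(y, s, p: ParameterSet, tmpl: StressorInput) -> BranchPoint:
    u = (s, tmpl.tg, tmpl.dtt, tmpl.kaua_mult)
    ev = np.linalg.eigvals(_jac_raw(y, p, *u))
    return BranchPoint(stress=float(s), state=ModelState.from_array(y),
                       stability=classify_stability(ev), eigenvalues=ev)


def _initial_tangent(y, s, p, tmpl, direction: float) -> np.ndarray:
    """Null-space tangent of the bordered Jacobian, oriented along stress."""
    u = (s, tmpl.tg, tmpl.dtt, tmpl.kaua_mult)
    J = _jac_raw(y, p, u[0] * 0 + s, tmpl.tg, tmpl.dtt, tmpl.kaua_mult)
    A = np.hstack([J, _drhs_dstress(y, p)[:, None]])
    _, _, vh = np.linalg.svd(A)
    t = vh[-1]
    if t[5] * direction < 0:
        t = -t
    return t / np.linalg.norm(t)


def _trace_branch(y0, s0, p: ParameterSet, tmpl: StressorInput,
                  s_range: tuple[float, float], direction: float,
                  ds0: float, ds_min: float, ds_max: float,
                  max_points: int, log: list[str]):
    """Trace one branch from (y0, s0); returns (points, fold stresses)."""
    s_lo, s_hi = s_range
    x = np.concatenate([y0, [s0]])
    tangent = _initial_tangent(y0, s0, p, tmpl, direction)
    points = [(x.copy(), tangent.copy())]
    folds: list[float] = []
    h = ds0
    while len(points) < max_points:
        x_prev, t_prev = points[-1]
        x_pred = x_prev + h * t_prev
        x_new = _corrector(x_pred, x_pred, t_prev, p, tmpl)
        if x_new is None:
            h *= 0.5
            if h < ds_min:
                log.append(
                    f"branch truncated at stress={x_prev[5]:.6g}:"
                    " step below minimum"
                )
                break
            continue
        t_new = x_new - x_prev
        nrm = np.linalg.norm(t_new)
        if nrm == 0.0:
            break
        t_new = t_new / nrm
        # fold: stress progression changes sign along arclength
        if t_prev[5] * t_new[5] < 0:
            folds.append(_refine_fold(x_prev, t_prev, h, p, tmpl, log))
        points.append((x_new.copy(), t_new.copy()))
        h = min(h * 1.3, ds_max)
        s = x_new[5]
        if s < s_lo - 1e-12 or s > s_hi + 1e-12:
            # clamp the endpoint exactly onto the range boundary
            s_clamp = s_lo if s < s_lo else s_hi
            y_cl = _solve_at_stress(x_new[:5], s_clamp, p, tmpl)
            if y_cl is not None:
                points[-1] = (np.concatenate([y_cl, [s_clamp]]), t_new)
            break
    return points, folds


def _refine_fold(x_from, tangent, h, p, tmpl, log) -> float:
    """Bisect the arclength step until the fold stress is pinned to FOLD_TOL."""
    lo, hi = 0.0, h
    t_lo = tangent
    x_lo = x_from
    s_fold = x_from[5]
    for _ in range(80):
        if hi - lo < 1e-12:
            break
        mid = 0.5 * (lo + hi)
        x_pred = x_lo + (mid - lo) * t_lo
        x_mid = _corrector(x_pred, x_pred, t_lo, p, tmpl)
        if x_mid is None:
            hi = mid
            continue
        t_mid = x_mid - x_lo
        nrm = np.linalg.norm(t_mid)
        if nrm == 0:
            break
        t_mid = t_mid / nrm
        if t_lo[5] * t_mid[5] < 0:
            hi = mid
        else:
            x_lo, t_lo, lo = x_mid, t_mid, mid
        s_fold = x_lo[5]
        if abs(hi - lo) * max(abs(t_lo[5]), 1e-3) < FOLD_TOL * 0.5:
            break
    return float(s_fold)


def continue_in_stress(params: ParameterSet,
                       input_template: StressorInput = StressorInput(),
                       stress_range: tuple[float, float] = (0.0, 60.0),
                       ds0: float = 0.1, ds_min: float = 1e-5,
                       ds_max: float = 1.0, max_points: int = 4000,
                       n_starts: int = 60, seed: int = 0) -> BifurcationDiagram:
    """Assemble all equilibrium branches over ``stress_range``.

    Branches are seeded from multi-start root finding at both ends of the
    range and traced inward/through folds by pseudo-arclength continuation.
    Duplicate coverage is merged by proximity.
    """
    params.validate()
    s_lo, s_hi = stress_range
    if s_hi <= s_lo:
        raise ValueError("stress_range must satisfy s_max > s_min")
    log: list[str] = []
    branches_raw: list[list[tuple[np.ndarray, np.ndarray]]] = []
    folds: list[float] = []

    seeds = []
    for s0, direction in ((s_lo, +1.0), (s_hi, -1.0)):
        inp = replace(input_template, stress=s0)
        for eq in find_equilibria(params, inp, n_starts=n_starts, seed=seed):
            seeds.append((eq.state.to_array(), s0, direction))

    for y0, s0, direction in seeds:
        x0 = np.concatenate([y0, [s0]])
        covered = False
        for br in branches_raw:
            d = min(np.linalg.norm(x0 - x) for x, _ in br)
            if d < 1e-4:
                covered = True
                break
        if covered:
            continue
        pts, br_folds = _trace_branch(
            y0, s0, params, input_template, stress_range, direction,
            ds0, ds_min, ds_max, max_points, log)
        branches_raw.append(pts)
        folds.extend(br_folds)

    branches = []
    for br in branches_raw:
        branches.append([
            _branch_point(x[:5], x[5], params, input_template) for x, _ in br
        ])
    folds = sorted(set(round(f, 6) for f in folds))
    return BifurcationDiagram(branches=branches, limit_points=list(folds),
                              stress_range=stress_range, log=log)


def _stable_intervals(diagram: BifurcationDiagram) -> list[tuple[float, float]]:
    """Stress extents of maximal stable sub-segments of each branch."""
    out = []
    for branch in diagram.branches:
        run: list[BranchPoint] = []
        for pt in branch + [None]:
            if pt is not None and pt.stability == "stable":
                run.append(pt)
            else:
                if len(run) >= 1:
                    ss = [p.stress for p in run]
                    out.append((min(ss), max(ss)))
                run = []
    return out


def bistable_interval(
        diagram: BifurcationDiagram) -> tuple[float, float] | None:
    """Maximal stress interval over which >= 2 stable branch points coexist."""
    intervals = _stable_intervals(diagram)
    if len(intervals) < 2:
        return None
    events = []
    for lo, hi in intervals:
        events.append((lo, +1))
        events.append((hi, -1))
    events.sort(key=lambda e: (e[0], -e[1]))
    best = None
    depth = 0
    start = None
    for s, d in events:
        depth += d
        if depth >= 2 and start is None:
            start = s
        elif depth < 2 and start is not None:
            if best is None or (s - start) > (best[1] - best[0]):
                best = (start, s)
            start = None
    if start is not None:
        s_end = diagram.stress_range[1]
        if best is None or (s_end - start) > (best[1] - best[0]):
            best = (start, s_end)
    if best is not None and best[1] - best[0] <= 0:
        return None
    return best


def dense_sweep(params: ParameterSet,
                input_template: StressorInput = StressorInput(),
                stress_range: tuple[float, float] = (0.0, 60.0),
                n_stress: int = 500, n_starts: int = 60,
                seed: int = 0, link_tol: float = 0.2) -> BifurcationDiagram:
    """Independent oracle: find_equilibria on a fine stress grid with
    nearest-neighbour branch linking."""
    s_vals = np.linspace(stress_range[0], stress_range[1], n_stress)
    open_branches: list[list[BranchPoint]] = []
    closed: list[list[BranchPoint]] = []
    for s in s_vals:
        inp = replace(input_template, stress=float(s))
        eqs = find_equilibria(params, inp, n_starts=n_starts, seed=seed)
        pts = [BranchPoint(stress=float(s), state=e.state,
                           eigenvalues=e.eigenvalues, stability=e.stability)
               for e in eqs]
        matched = [False] * len(pts)
        still_open = []
        for br in open_branches:
            prev = br[-1].state.to_array()
            best_j, best_d = None, np.inf
            for j, pt in enumerate(pts):
                if matched[j]:
                    continue
                d = np.max(np.abs(pt.state.to_array() - prev))
                if d < best_d:
                    best_j, best_d = j, d
            if best_j is not None and best_d < link_tol:
                br.append(pts[best_j])
                matched[best_j] = True
                still_open.append(br)
            else:
                closed.append(br)
        for j, pt in enumerate(pts):
            if not matched[j]:
                still_open.append([pt])
        open_branches = still_open
    closed.extend(open_branches)
    # folds of the oracle: branch ends interior to the range
    folds = []
    for br in closed:
        for end in (br[0], br[-1]):
            if (stress_range[0] + 1e-9 < end.stress
                    < stress_range[1] - 1e-9):
                folds.append(end.stress)
    return BifurcationDiagram(branches=closed, limit_points=sorted(folds),
                              stress_range=stress_range,
                              log=["dense-sweep oracle"])
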