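"""Equilibrium continuation and bifurcation detection.

Equilibria of every 1D model reduce to a scalar root problem: at a fixed
point the velocity is zero and the receptors sit at their local steady
states, so x* solves ``equilibrium_force(x) = 0``.  Stability comes from
the eigenvalues of the Jacobian at the reconstructed state (restricted to
the dynamical variables for reduced variants).

Continuation is natural-parameter: sweep the free parameter, re-locate the
equilibrium closest to the previous one, and watch the spectrum.  A Hopf
point is a sign change of the largest real part over the complex-conjugate
eigenvalue pairs (refined by bisection); a fold is the disappearance of the
followed branch (refined by bisection on branch existence).  In the models
treated here, oscillations switch on at a supercritical Hopf (H1) as the
zone separation k grows, and switch off where a stable equilibrium branch
is (re)born at a fold whose newborn branch carries a complex pair grazing
zero — the subcritical-Hopf/fold pair the diagrams label H2/LP2.  The
upper boundary reported by :func:`oscillatory_window` is the parameter at
which a stable equilibrium first reappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "Equilibrium",
    "BifurcationPoint",
    "find_equilibrium",
    "continue_equilibrium",
    "oscillatory_window",
    "trace_hopf_boundary",
    "has_stable_equilibrium",
    "classify_parameter_point",
]

NEWTON_TOL = 1e-10
PARAM_TOL = 1e-3
HOPF_TOL = 1e-3


@dataclass
class Equilibrium:
    """A located fixed point with its spectrum."""

    state: np.ndarray
    param_value: float
    eigenvalues: np.ndarray
    stable: bool
    residual: float = 0.0

    @property
    def x(self) -> float:
        return float(self.state[0])


@dataclass
class BifurcationPoint:
    kind: str  # 'hopf' | 'fold'
    param_value: float
    state: np.ndarray
    label: str = ""
    info: dict[str, Any] = field(default_factory=dict)


def _active_eigenvalues(model, state) -> np.ndarray:
    J = model.jacobian(state)
    idx = np.asarray(model.active_index, dtype=int)
    return np.linalg.eigvals(J[np.ix_(idx, idx)])


def _max_re_complex(eigs: np.ndarray) -> float | None:
    cplx = eigs[np.abs(eigs.imag) > 1e-9]
    if cplx.size == 0:
        return None
    return float(cplx.real.max())


def find_equilibrium(model, initial_guess, newton_tol: float = NEWTON_TOL,
                     max_iter: int = 60, param_value: float = np.nan
                     ) -> Equilibrium:
    """Newton iteration on ``rhs(y) = 0`` from ``initial_guess``.

    Iterates on the model's dynamical variables (frozen components of
    reduced variants are left untouched).  Raises ``RuntimeError`` with the
    final residual on non-convergence.
    """
    y = np.asarray(initial_guess, dtype=float).copy()
    idx = np.asarray(model.active_index, dtype=int)
    for _ in range(max_iter):
        r = np.asarray(model.rhs(0.0, y))[idx]
        if np.max(np.abs(r)) < newton_tol:
            break
        J = model.jacobian(y)[np.ix_(idx, idx)]
        try:
            dy = np.linalg.solve(J, r)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular Jacobian in Newton step: {exc}")
        y[idx] -= dy
    else:
        res = float(np.max(np.abs(np.asarray(model.rhs(0.0, y))[idx])))
        raise RuntimeError(
            f"Newton did not converge after {max_iter} iterations; "
            f"residual={res:.3e}")
    eigs = _active_eigenvalues(model, y)
    res = float(np.max(np.abs(np.asarray(model.rhs(0.0, y))[idx])))
    return Equilibrium(state=y, param_value=param_value, eigenvalues=eigs,
                       stable=bool(np.all(eigs.real < 0)), residual=res)


def _equilibrium_near(model, x_prev: float, param_value: float,
                      jump_tol: float = 8.0) -> Equilibrium | None:
    """Locate the equilibrium nearest ``x_prev``; None if the branch ended."""
    roots = model.equilibria_x()
    if roots.size == 0:
        return None
    x = roots[np.argmin(np.abs(roots - x_prev))]
    if abs(x - x_prev) > jump_tol:
        return None
    eq = find_equilibrium(model, model.equilibrium_state(x),
                          param_value=param_value)
    return eq


def continue_equilibrium(model_factory: Callable[[float], Any],
                         p_range: Sequence[float], step: float = 0.25,
                         x_start: float = 0.0, param_tol: float = PARAM_TOL,
                         jump_tol: float = 8.0
                         ) -> tuple[list[Equilibrium], list[BifurcationPoint]]:
    """Follow an equilibrium branch over ``p_range``.

    ``model_factory(p)`` builds the model at parameter value ``p``.  Returns
    the branch (one :class:`Equilibrium` per step until the branch ends) and
    the detected bifurcation points: Hopf points labelled H1, H2, ... in
    order of detection, and the terminal fold (labelled LP) if the branch
    disappears inside the range.
    """
    p0, p1 = float(p_range[0]), float(p_range[1])
    ps = np.arange(p0, p1 + step * 1e-9, step)
    branch: list[Equilibrium] = []
    points: list[BifurcationPoint] = []
    x_prev = x_start
    prev_eq: Equilibrium | None = None
    n_hopf = 0

    def hopf_fn(p, x_guess):
        eq = _equilibrium_near(model_factory(p), x_guess, p, jump_tol)
        if eq is None:
            return None
        m = _max_re_complex(eq.eigenvalues)
        return (m, eq)

    for p in ps:
        model = model_factory(p)
        eq = _equilibrium_near(model, x_prev, p,
                               jump_tol if prev_eq is not None else np.inf)
        if eq is None:
            if prev_eq is not None:
                # branch ended: bisect the fold location
                lo, hi = prev_eq.param_value, p
                xg = prev_eq.x
                last = prev_eq
                while hi - lo > param_tol:
                    mid = 0.5 * (lo + hi)
                    e = _equilibrium_near(model_factory(mid), xg, mid,
                                          jump_tol)
                    if e is None:
                        hi = mid
                    else:
                        lo, xg, last = mid, e.x, e
                points.append(BifurcationPoint(
                    kind="fold", param_value=lo, state=last.state,
                    label="LP", info={"eigenvalues": last.eigenvalues}))
            break
        # Hopf: sign change of the complex-pair max real part
        if prev_eq is not None:
            m_prev = _max_re_complex(prev_eq.eigenvalues)
            m_now = _max_re_complex(eq.eigenvalues)
            if (m_prev is not None and m_now is not None
                    and np.sign(m_prev) != np.sign(m_now) and m_prev != 0):
                lo, hi = prev_eq.param_value, p
                s_lo = np.sign(m_prev)
                xg = prev_eq.x
                best = eq
                while hi - lo > param_tol:
                    mid = 0.5 * (lo + hi)
                    r = hopf_fn(mid, xg)
                    if r is None:
                        break
                    m_mid, e_mid = r
                    if m_mid is None:
                        break
                    if np.sign(m_mid) == s_lo:
                        lo, xg = mid, e_mid.x
                    else:
                        hi, best = mid, e_mid
                n_hopf += 1
                points.append(BifurcationPoint(
                    kind="hopf", param_value=0.5 * (lo + hi),
                    state=best.state, label=f"H{n_hopf}",
                    info={"max_re_pair": _max_re_complex(best.eigenvalues)}))
        branch.append(eq)
        x_prev = eq.x
        prev_eq = eq
    return branch, points


def has_stable_equilibrium(model) -> bool:
    """True if any equilibrium of the model is linearly stable."""
    for x in model.equilibria_x():
        eigs = _active_eigenvalues(model, model.equilibrium_state(x))
        if np.all(eigs.real < 0):
            return True
    return False


def classify_parameter_point(model) -> str:
    """'steady_state' if a stable equilibrium exists, else 'oscillatory'.

    With no stable fixed point anywhere, bounded trajectories must approach
    a non-equilibrium attractor (for these models: a limit cycle or a more
    complex oscillatory set).
    """
    return "steady_state" if has_stable_equilibrium(model) else "oscillatory"


@dataclass
class BranchPoint:
    """One point of an arclength-traced equilibrium curve in (p, x)."""

    param_value: float
    x: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stable: bool


def _curve_point(model_factory, p, x) -> BranchPoint:
    model = model_factory(p)
    state = model.equilibrium_state(x)
    eigs = _active_eigenvalues(model, state)
    return BranchPoint(param_value=float(p), x=float(x), state=state,
                       eigenvalues=eigs, stable=bool(np.all(eigs.real < 0)))


def _correct_on_normal(model_factory, u_pred, normal, ds, tol=1e-10):
    """Solve equilibrium_force = 0 along ``u_pred + s * normal``.

    1D Newton with numerical derivative, bracketing fallback; returns the
    corrected (p, x) or None.
    """
    def f(s):
        p, x = u_pred + s * normal
        return float(model_factory(p).equilibrium_force(x))

    s = 0.0
    fs = f(s)
    for _ in range(30):
        if abs(fs) < tol:
            return u_pred + s * normal
        h = 1e-7 * (1.0 + abs(s))
        d = (f(s + h) - f(s - h)) / (2 * h)
        if d == 0 or not np.isfinite(d):
            break
        s_new = s - fs / d
        if abs(s_new - s) > 2.0 * ds:  # diverging: give up on Newton
            break
        s, fs = s_new, f(s_new)
    # bracket fallback
    from scipy.optimize import brentq
    for half in (ds, 2 * ds, 4 * ds):
        a, b = -half, half
        fa, fb = f(a), f(b)
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb < 0:
            s = brentq(f, a, b, xtol=1e-12)
            return u_pred + s * normal
    return None


def trace_branch(model_factory: Callable[[float], Any],
                 p_range: Sequence[float], x_start: float = 0.0,
                 ds: float = 0.25, max_points: int = 20000
                 ) -> list[BranchPoint]:
    """Pseudo-arclength continuation of the connected equilibrium curve.

    Follows the scalar equilibrium condition F(x; p) = 0 through folds in
    ``p`` (where the curve turns back), starting from the equilibrium
    nearest ``x_start`` at ``p_range[0]`` and heading toward increasing p.
    Stops when p leaves ``p_range`` (with a small margin) or the point
    budget is exhausted.
    """
    p0, p1 = float(p_range[0]), float(p_range[1])
    margin = 0.05 * (p1 - p0)
    model = model_factory(p0)
    roots = model.equilibria_x()
    if roots.size == 0:
        return []
    x = float(roots[np.argmin(np.abs(roots - x_start))])
    pts = [_curve_point(model_factory, p0, x)]
    u = np.array([p0, x])
    tangent = None
    # first tangent by implicit differentiation via a small natural step
    dp = min(ds, 1e-3 * (p1 - p0))
    nxt = _correct_on_normal(model_factory, np.array([p0 + dp, x]),
                             np.array([0.0, 1.0]), ds)
    if nxt is None:
        return pts
    tangent = nxt - u
    tangent /= np.linalg.norm(tangent)
    while len(pts) < max_points:
        u_pred = u + ds * tangent
        normal = np.array([-tangent[1], tangent[0]])
        u_new = _correct_on_normal(model_factory, u_pred, normal, ds)
        if u_new is None:
            # halve the step a few times before giving up
            ok = False
            for _ in range(6):
                u_pred = u + 0.5 * (u_pred - u)
                u_new = _correct_on_normal(model_factory, u_pred, normal,
                                           ds)
                if u_new is not None:
                    ok = True
                    break
            if not ok:
                break
        new_tangent = u_new - u
        norm = np.linalg.norm(new_tangent)
        if norm < 1e-12:
            break
        new_tangent /= norm
        if np.dot(new_tangent, tangent) < 0:
            new_tangent = -new_tangent  # never reverse direction
        u, tangent = u_new, new_tangent
        pts.append(_curve_point(model_factory, u[0], u[1]))
        if u[0] > p1 + margin or u[0] < p0 - margin:
            break
    return pts


def _refine_flip(model_factory, a: BranchPoint, b: BranchPoint,
                 param_tol: float = PARAM_TOL) -> BranchPoint:
    """Bisect a stability flip between two adjacent curve points."""
    ua = np.array([a.param_value, a.x])
    ub = np.array([b.param_value, b.x])
    pa = a
    for _ in range(60):
        if (abs(ub[0] - ua[0]) < param_tol
                and np.linalg.norm(ub - ua) < 10 * param_tol):
            break
        mid = 0.5 * (ua + ub)
        chord = ub - ua
        n = np.array([-chord[1], chord[0]])
        n /= np.linalg.norm(n)
        um = _correct_on_normal(model_factory, mid,
                                n, max(np.linalg.norm(chord), param_tol))
        if um is None:
            break
        pm = _curve_point(model_factory, um[0], um[1])
        if pm.stable == pa.stable:
            ua, pa = um, pm
        else:
            ub = um
    return _curve_point(model_factory, ub[0], ub[1])


def oscillatory_window(model_factory: Callable[[float], Any],
                       p_range: Sequence[float], step: float = 0.25,
                       x_start: float = 0.0, param_tol: float = PARAM_TOL,
                       hopf_tol: float = HOPF_TOL
                       ) -> tuple[BifurcationPoint | None,
                                  BifurcationPoint | None]:
    """Onset (H1) and offset (H2) of the oscillatory parameter window.

    Traces the connected equilibrium curve with pseudo-arclength
    continuation and reads off the stability transitions along it.  Onset:
    the first stable->unstable transition (the supercritical Hopf H1).
    Offset: the last unstable->stable transition along the curve — the
    point where the stable equilibrium branch is (re)born.  In these
    models the offset is a subcritical Hopf grazing a fold: if the complex
    pair at the refined point has |Re| < hopf_tol it is reported as kind
    'hopf', otherwise as the coincident fold; either way the label is H2,
    matching the diagrams.  Ends not found in range are None.
    """
    pts = trace_branch(model_factory, p_range, x_start=x_start, ds=step)
    if len(pts) < 2:
        return None, None
    flips = []
    for a, b in zip(pts[:-1], pts[1:]):
        if a.stable != b.stable:
            flips.append((a, b))
    onset = offset = None
    # onset: first destabilization
    for a, b in flips:
        if a.stable and not b.stable:
            ref = _refine_flip(model_factory, a, b, param_tol)
            graze = _max_re_complex(ref.eigenvalues)
            onset = BifurcationPoint(
                kind="hopf", param_value=ref.param_value, state=ref.state,
                label="H1", info={"x": ref.x, "grazing_re_pair": graze})
            break
    # offset: last restabilization
    for a, b in reversed(flips):
        if (not a.stable) and b.stable:
            ref = _refine_flip(model_factory, a, b, param_tol)
            graze = _max_re_complex(ref.eigenvalues)
            kind = ("hopf" if graze is not None and abs(graze) < hopf_tol
                    else "fold")
            offset = BifurcationPoint(
                kind=kind, param_value=ref.param_value, state=ref.state,
                label="H2", info={"x": ref.x, "grazing_re_pair": graze})
            break
    return onset, offset


def trace_hopf_boundary(model_factory_2d: Callable[[float, float], Any],
                        p1_range: Sequence[float], p2_values: Sequence[float],
                        step: float = 0.25, param_tol: float = PARAM_TOL
                        ) -> list[dict]:
    """Trace the oscillatory region boundary in a 2-parameter plane.

    For each value of the second parameter, follow the primary equilibrium
    branch in the first parameter and record the interval over which it is
    unstable (first Hopf to the terminal fold or last unstable point) —
    the dotted segment of the one-parameter diagrams, over which
    oscillations exist.  Rows with None mark gaps (no instability window
    at that p2), recorded rather than raised.
    """
    rows = []
    for p2 in p2_values:
        branch, points = continue_equilibrium(
            lambda p1: model_factory_2d(p1, p2), p1_range, step=step,
            param_tol=param_tol)
        onset = next((pt.param_value for pt in points
                      if pt.kind == "hopf"), None)
        offset = None
        if onset is not None:
            fold = next((pt.param_value for pt in points
                         if pt.kind == "fold"), None)
            unstable = [eq.param_value for eq in branch if not eq.stable]
            cands = [v for v in (fold, max(unstable, default=None))
                     if v is not None]
            offset = max(cands) if cands else None
        rows.append({"p2": float(p2), "p1_onset": onset,
                     "p1_offset": offset})
    return rows
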