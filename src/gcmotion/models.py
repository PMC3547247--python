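"""Right-hand sides for the B-cell migration models.

All variants couple cell mechanics to chemokine-receptor regulation.  The
cell state is ``y = [x, v, r1, r2]``: displacement along the zone axis,
velocity, and the surface densities of the two chemokine receptors (CXCR4,
which binds CXCL12 = f1, and CXCR5, which binds CXCL13 = f2).

Toy model
    dr_i/dt = pi_i - r_i f_i(x) - delta_i r_i
    dx/dt   = v
    dv/dt   = r1 f1'(x) + r2 f2'(x) - gamma v

Receptors are synthesized at rate pi, degraded constitutively at rate delta,
and down-regulated at a rate proportional to the local cognate chemokine
concentration.  Velocity responds to the receptor-weighted chemokine
gradients against a drag gamma.

Phenomenological (full) model
    dr_i/dt = pi_i - r_i tau_i kappa_i f_i(x) / (1 + kappa_i f_i(x))
              - delta_i r_i
    dx/dt   = v
    dv/dt   = chi (S1 + S2) - gamma v,   S_i = zeta r_i f_i'(x)
                                               / (1 + eps_i f_i(x))^2

The receptor equation is the quasi-steady-state reduction of the mass-action
GPCR trafficking scheme (see :func:`mass_action_rhs`): kappa is a rescaled
equilibrium association constant and delta + tau the removal rate of bound
receptor.  The chemotactic signal S_i is the receptor density times the
spatial gradient of the saturable ligand signal f/(1 + eps f); eps is an
effective association constant kept distinct from kappa so receptor
regulation and signal transduction can couple differently to occupancy.

The single-receptor variant freezes r2 (dr2/dt = 0), leaving only CXCR4
regulated by its field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .fields import ChemokineEnvironment

__all__ = [
    "ToyParams",
    "MassActionParams",
    "ReceptorParams",
    "ChemotaxisParams",
    "ToyModel",
    "FullModel",
    "SingleReceptorModel",
    "toy_receptor_steady_state",
    "receptor_rhs",
    "receptor_steady_state",
    "reduced_velocity_rhs",
    "reduced_equilibria",
    "mass_action_rhs",
    "chemotactic_signal",
    "finite_difference_jacobian",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyParams:
    """Toy-model rates: synthesis pi_i, degradation delta_i, drag gamma."""

    pi1: float
    pi2: float
    delta1: float
    delta2: float
    gamma: float

    def __post_init__(self):
        for name in ("pi1", "pi2", "delta1", "delta2", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class MassActionParams:
    """Mass-action GPCR trafficking rates.

    k_on/k_off: ligand association/dissociation; mu: internalization of
    bound receptor; beta: recycling of internalized receptor; delta:
    degradation of internalized receptor; pi: synthesis; tau: first-order
    removal of unbound receptor (keeps U finite without ligand).
    """

    k_on: float
    k_off: float
    mu: float
    beta: float
    delta: float
    pi: float
    tau: float

    def __post_init__(self):
        for name in ("k_on", "k_off", "mu", "beta", "delta", "pi", "tau"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ReceptorParams:
    """Reduced receptor equation rates: pi, tau, kappa, delta."""

    pi: float
    tau: float
    kappa: float
    delta: float

    def __post_init__(self):
        for name in ("pi", "tau", "kappa", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ChemotaxisParams:
    """Chemotaxis parameters.

    chi: responsiveness; epsilon1/epsilon2: effective association constants
    of the saturable signal; zeta: signal scale factor; gamma: drag; sigma:
    Langevin noise intensity on velocity (0 = deterministic).
    """

    chi: float
    epsilon1: float
    epsilon2: float
    gamma: float
    zeta: float = 1.0
    sigma: float = 0.0

    def __post_init__(self):
        for name in ("chi", "epsilon1", "epsilon2", "gamma", "zeta", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def toy_receptor_steady_state(pi: float, delta: float, f_local: float) -> float:
    """Steady-state receptor density pi / (delta + f) of the toy model.

    Monotonically decreasing in the local chemokine concentration: receptor
    loss is strongest where cognate chemokine is most abundant.
    """
    denom = delta + np.asarray(f_local, dtype=float)
    if not np.all(denom > 0):
        raise ZeroDivisionError(
            "toy receptor steady state requires delta + f > 0")
    out = pi / denom
    return float(out) if out.ndim == 0 else out


def receptor_rhs(r, f_local, rp: ReceptorParams):
    """dr/dt = pi - r tau kappa f/(1 + kappa f) - delta r.

    Saturates in f: the loss rate tends to (tau + delta) as f -> inf and to
    delta as f -> 0.
    """
    occ = rp.kappa * f_local / (1.0 + rp.kappa * f_local)
    return rp.pi - r * rp.tau * occ - rp.delta * r


def receptor_steady_state(rp: ReceptorParams, f_local):
    """Closed-form fixed point of :func:`receptor_rhs` at fixed f."""
    occ = rp.kappa * f_local / (1.0 + rp.kappa * f_local)
    return rp.pi / (rp.delta + rp.tau * occ)


def reduced_velocity_rhs(x, s, env: ChemokineEnvironment):
    """Undamped reduced velocity equation dv/dt = s f1'(x) + f2'(x).

    ``s = r1/r2`` is the (rescaled) receptor ratio, treated as a parameter.
    The sign structure of this scalar field in x determines whether the
    dark zone, the light zone, or both are attracting: small s leaves a
    single stable zero at the f2 centre, intermediate s is bistable, and
    large s leaves only the zero near the f1 centre.
    """
    g1, g2 = env.gradients(x)
    return s * g1 + g2


def reduced_equilibria(s, env: ChemokineEnvironment, x_range=None,
                       n_scan: int = 12001):
    """Equilibria of the reduced model and their stability.

    Returns a list of ``(x, stable)`` pairs.  For the conservative system
    x'' = F(x) a zero of F with F'(x) < 0 is a potential-well minimum
    (elliptically stable); F'(x) > 0 marks a saddle.
    """
    from scipy.optimize import brentq
    if x_range is None:
        pad = 4 * max(env.f1.width, env.f2.width)
        x_range = (min(env.f1.center, env.f2.center) - pad,
                   max(env.f1.center, env.f2.center) + pad)
    xs = np.linspace(x_range[0], x_range[1], n_scan)
    F = lambda x: reduced_velocity_rhs(x, s, env)  # noqa: E731
    Fs = np.asarray(F(xs))
    roots = []
    for i in range(n_scan - 1):
        if Fs[i] == 0.0:
            roots.append(float(xs[i]))
        elif Fs[i] * Fs[i + 1] < 0:
            roots.append(brentq(F, xs[i], xs[i + 1], xtol=1e-12))
    out = []
    for r in roots:
        h = 1e-6 * (1 + abs(r))
        dF = (F(r + h) - F(r - h)) / (2 * h)
        out.append((float(r), bool(dF < 0)))
    return out


def mass_action_rhs(state, L, mp: MassActionParams):
    """Mass-action GPCR trafficking: state = [U, B, I], ligand L.

    dU/dt = pi - k_on L U + k_off B + beta I - tau U
    dB/dt = k_on L U - k_off B - mu B
    dI/dt = mu B - beta I - delta I

    Unbound receptor U binds ligand to become bound receptor B, which is
    internalized (I) and then recycled or degraded.  Total receptor obeys
    d(U+B+I)/dt = pi - tau U - delta I.
    """
    U, B, I = state
    bind = mp.k_on * L * U
    dU = mp.pi - bind + mp.k_off * B + mp.beta * I - mp.tau * U
    dB = bind - mp.k_off * B - mp.mu * B
    dI = mp.mu * B - mp.beta * I - mp.delta * I
    return np.array([dU, dB, dI])


def chemotactic_signal(r, f, fgrad, epsilon, zeta=1.0):
    """Saturable chemotactic signal S = zeta r f' / (1 + eps f)^2.

    This is ``r`` times the spatial gradient of the saturable ligand signal
    f/(1 + eps f): the directional drive saturates where ligand is abundant,
    so a receptor contributes most force on the flank of its cognate field.
    """
    return zeta * r * fgrad / (1.0 + epsilon * f) ** 2


def finite_difference_jacobian(rhs, y, rel_step=1e-6):
    """Central-difference Jacobian of ``rhs(y)`` with state-scaled steps."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(y[j]))
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (np.asarray(rhs(y + e)) - np.asarray(rhs(y - e))) / (2 * h)
    return J


# --------------------------------------------------------------------------
# model classes
# --------------------------------------------------------------------------

class _Model1D:
    """Shared plumbing for the 1D cell models (state [x, v, r1, r2])."""

    n_dim = 4
    #: indices of dynamical state variables (frozen ones excluded); the
    #: stability analysis restricts the Jacobian to these.
    active_index = (0, 1, 2, 3)
    env: ChemokineEnvironment

    # subclasses define: _receptor_dot(r1, r2, F1, F2), _force(r1, r2, x),
    # receptor_steady_states(x), drag (gamma)

    def rhs(self, t, y):
        """Time-derivative of the state; signature matches solve_ivp."""
        x, v, r1, r2 = y
        F1, F2 = self.env.values(x)
        dr1, dr2 = self._receptor_dot(r1, r2, F1, F2)
        dv = self._force(r1, r2, x) - self.drag * v
        return np.array([v, dv, dr1, dr2])

    def jacobian(self, y, rel_step=1e-6):
        """Jacobian at state y (finite differences unless overridden)."""
        return finite_difference_jacobian(lambda z: self.rhs(0.0, z), y,
                                          rel_step=rel_step)

    def equilibrium_force(self, x):
        """Net chemotactic force at x with receptors at steady state.

        Equilibria of the model are exactly (x*, 0, r1ss(x*), r2ss(x*)) with
        equilibrium_force(x*) = 0, which reduces equilibrium location to a
        scalar root problem.
        """
        r1, r2 = self.receptor_steady_states(x)
        return self._force(r1, r2, x)

    def equilibrium_state(self, x):
        r1, r2 = self.receptor_steady_states(x)
        return np.array([float(x), 0.0, float(r1), float(r2)])

    def equilibria_x(self, x_range=None, n_scan=8001):
        """All equilibrium displacements in x_range by sign-change scan."""
        from scipy.optimize import brentq
        if x_range is None:
            lo = min(self.env.f1.center, self.env.f2.center) - 3 * max(
                self.env.f1.width, self.env.f2.width)
            hi = max(self.env.f1.center, self.env.f2.center) + 3 * max(
                self.env.f1.width, self.env.f2.width)
        else:
            lo, hi = x_range
        xs = np.linspace(lo, hi, n_scan)
        Fs = np.asarray(self.equilibrium_force(xs))
        roots = []
        for i in range(n_scan - 1):
            if Fs[i] == 0.0:
                roots.append(xs[i])
            elif Fs[i] * Fs[i + 1] < 0:
                roots.append(brentq(self.equilibrium_force, xs[i], xs[i + 1],
                                    xtol=1e-12))
        return np.array(roots)


class ToyModel(_Model1D):
    """Toy receptor/chemotaxis model (linear down-regulation, bare gradient)."""

    def __init__(self, env: ChemokineEnvironment, params: ToyParams):
        self.env = env
        self.params = params
        self.drag = params.gamma

    def _receptor_dot(self, r1, r2, F1, F2):
        p = self.params
        return (p.pi1 - r1 * F1 - p.delta1 * r1,
                p.pi2 - r2 * F2 - p.delta2 * r2)

    def _force(self, r1, r2, x):
        g1, g2 = self.env.gradients(x)
        return r1 * g1 + r2 * g2

    def receptor_steady_states(self, x):
        F1, F2 = self.env.values(x)
        p = self.params
        return (toy_receptor_steady_state(p.pi1, p.delta1, F1),
                toy_receptor_steady_state(p.pi2, p.delta2, F2))

    def jacobian(self, y, rel_step=None):
        """Analytic Jacobian of the toy model."""
        x, v, r1, r2 = y
        F1, F2 = self.env.values(x)
        g1, g2 = self.env.gradients(x)
        h1 = self.env.f1.second_derivative(x)
        h2 = self.env.f2.second_derivative(x)
        p = self.params
        return np.array([
            [0.0, 1.0, 0.0, 0.0],
            [r1 * h1 + r2 * h2, -p.gamma, g1, g2],
            [-r1 * g1, 0.0, -(F1 + p.delta1), 0.0],
            [-r2 * g2, 0.0, 0.0, -(F2 + p.delta2)],
        ])

    def replace(self, *, env=None, params=None, **updates):
        p = self.params if params is None else params
        if updates:
            p = _dc_replace(p, **updates)
        return ToyModel(env if env is not None else self.env, p)


class FullModel(_Model1D):
    """Phenomenological model: saturable receptor loss + saturable signal."""

    def __init__(self, env: ChemokineEnvironment, rp1: ReceptorParams,
                 rp2: ReceptorParams, cp: ChemotaxisParams):
        self.env = env
        self.rp1 = rp1
        self.rp2 = rp2
        self.cp = cp
        self.drag = cp.gamma

    def _receptor_dot(self, r1, r2, F1, F2):
        return (receptor_rhs(r1, F1, self.rp1),
                receptor_rhs(r2, F2, self.rp2))

    def _force(self, r1, r2, x):
        F1, F2 = self.env.values(x)
        g1, g2 = self.env.gradients(x)
        cp = self.cp
        S1 = chemotactic_signal(r1, F1, g1, cp.epsilon1, cp.zeta)
        S2 = chemotactic_signal(r2, F2, g2, cp.epsilon2, cp.zeta)
        return cp.chi * (S1 + S2)

    def receptor_steady_states(self, x):
        F1, F2 = self.env.values(x)
        return (receptor_steady_state(self.rp1, F1),
                receptor_steady_state(self.rp2, F2))

    def replace(self, *, env=None, rp1=None, rp2=None, cp=None):
        return type(self)(env if env is not None else self.env,
                          rp1 if rp1 is not None else self.rp1,
                          rp2 if rp2 is not None else self.rp2,
                          cp if cp is not None else self.cp)


class SingleReceptorModel(FullModel):
    """Variant with CXCR5 frozen: dr2/dt = 0, only CXCR4 is regulated.

    r2 stays at whatever value it is initialized with (conventionally the
    full model's equilibrium value, so the algebraic fixed points coincide
    with the full model's).
    """

    active_index = (0, 1, 2)  # dynamical dimensions: x, v, r1

    def _receptor_dot(self, r1, r2, F1, F2):
        dr1, _ = super()._receptor_dot(r1, r2, F1, F2)
        return dr1, 0.0

    def jacobian(self, y, rel_step=1e-6):
        J = super().jacobian(y, rel_step=rel_step)
        J[3, :] = 0.0  # frozen r2 contributes a structural zero row
        return J
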