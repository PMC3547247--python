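"""Deterministic and stochastic time integration.

Deterministic trajectories use scipy's adaptive solvers (default tolerances
rtol=1e-8, atol=1e-10, dense output sampled at the requested times).  The
Langevin model is integrated with fixed-step Euler-Maruyama: the drift is
the deterministic right-hand side and additive Gaussian noise of intensity
sigma acts on the velocity components only (receptors and position receive
no direct noise).  Runs are bitwise reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["Trajectory", "integrate_ode", "integrate_sde"]


@dataclass
class Trajectory:
    """Time-ordered states of one cell plus run metadata.

    ``states`` has one row per time point; ``columns`` names the state
    components (1D: x, v, r1, r2; 3D: x, y, z, vx, vy, vz, r1, r2).
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...] = ("x", "v", "r1", "r2")
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape[0] != self.times.size:
            raise ValueError("times and states must align (one row per time)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite values")
        if self.states.shape[1] != len(self.columns):
            raise ValueError("state width does not match columns")

    def __len__(self):
        return self.times.size

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time", self.times)
        if "cell_id" in self.meta:
            df["cell_id"] = self.meta["cell_id"]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c not in ("time", "cell_id")]
        m = dict(meta or {})
        if "cell_id" in df.columns:
            m.setdefault("cell_id", int(df["cell_id"].iloc[0]))
        return cls(times=df["time"].to_numpy(),
                   states=df[cols].to_numpy(), columns=tuple(cols), meta=m)


class IntegrationError(RuntimeError):
    pass


def integrate_ode(rhs: Callable, state0: Sequence[float], t_span,
                  t_eval=None, rtol: float = 1e-8, atol: float = 1e-10,
                  method: str = "LSODA", columns=("x", "v", "r1", "r2"),
                  meta: dict | None = None, max_step: float = np.inf
                  ) -> Trajectory:
    """Adaptive integration of ``dy/dt = rhs(t, y)``.

    Raises :class:`IntegrationError` with the failing time if the solver
    cannot complete the span (stiffness, blow-up).
    """
    state0 = np.asarray(state0, dtype=float)
    if not np.all(np.isfinite(rhs(t_span[0], state0))):
        raise ValueError("rhs is not finite at the initial state")
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 1000)
    sol = solve_ivp(rhs, t_span, state0, t_eval=t_eval, rtol=rtol, atol=atol,
                    method=method, dense_output=False, max_step=max_step)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t_span[0]}:"
            f" {sol.message}")
    m = {"integrator": method, "rtol": rtol, "atol": atol}
    m.update(meta or {})
    return Trajectory(times=sol.t, states=sol.y.T, columns=tuple(columns),
                      meta=m)


def integrate_sde(rhs: Callable, state0: Sequence[float], t_span,
                  dt: float, sigma: float, seed: int,
                  noise_index=(1,), t_eval=None,
                  columns=("x", "v", "r1", "r2"), meta: dict | None = None,
                  rng: np.random.Generator | None = None) -> Trajectory:
    """Euler-Maruyama integration with additive velocity noise.

    Each step advances the deterministic drift by ``dt`` and adds
    ``sigma * sqrt(dt) * N(0,1)`` to every component listed in
    ``noise_index`` (default: the velocity of the 1D state).  With
    ``sigma=0`` this is plain fixed-step Euler and converges to the ODE
    solution at first order in dt.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    t0, t1 = float(t_span[0]), float(t_span[1])
    n_steps = int(np.ceil((t1 - t0) / dt - 1e-12))
    y = np.asarray(state0, dtype=float).copy()
    noise_index = np.asarray(noise_index, dtype=int)

    if t_eval is None:
        stride = max(1, n_steps // 2000)
    else:
        t_eval = np.asarray(t_eval, dtype=float)

    times = [t0]
    states = [y.copy()]
    t = t0
    next_eval = 1  # index into t_eval when explicit sample times are given
    for i in range(n_steps):
        h = min(dt, t1 - t)
        drift = np.asarray(rhs(t, y))
        y = y + h * drift
        if sigma > 0:
            y[noise_index] += sigma * np.sqrt(h) * rng.standard_normal(
                noise_index.size)
        t = t + h
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={t:.6g}; dt={dt} may be too large")
        if t_eval is None:
            if (i + 1) % stride == 0 or i == n_steps - 1:
                times.append(t)
                states.append(y.copy())
        else:
            hit = False
            while next_eval < t_eval.size and t >= t_eval[next_eval] - 1e-12:
                hit = True
                next_eval += 1
            if hit:
                times.append(t)
                states.append(y.copy())
    m = {"integrator": "euler-maruyama", "dt": dt, "sigma": sigma,
         "seed": seed}
    m.update(meta or {})
    return Trajectory(times=np.array(times), states=np.array(states),
                      columns=tuple(columns), meta=m)
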