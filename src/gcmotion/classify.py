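"""Trajectory phenotyping.

Sorts simulated displacement traces into the qualitative classes the 1D
models produce: convergence to a fixed point, damped oscillations, and
sustained oscillations that are symmetric or asymmetric between the zones,
confined to one zone (intrazonal), "nested" (small sub-threshold loops
riding on large inter-zonal excursions), or chaotic.

The decision tree works on the post-transient displacement x(t):

1. terminal variance below tolerance            -> fixed_point
2. exponentially decaying peak envelope         -> damped
3. irregular inter-peak intervals AND positive
   largest-Lyapunov estimate                    -> chaotic
4. all extrema strictly on one side of x=0      -> intrazonal
5. an interior extremum on the wrong side of
   the midline (a local max below 0 or local
   min above 0), i.e. a loop that fails to
   cross between the zones                      -> nested
6. zone-residence fractions and cycle mean
   near-balanced                                -> periodic_symmetric
7. otherwise                                    -> periodic_asymmetric

Chaos needs BOTH irregular peak spacing and a positive Lyapunov estimate;
irregularity alone also occurs for long multi-loop limit cycles and for
long transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .integrate import Trajectory

__all__ = [
    "TrajectoryPhenotype",
    "classify_trajectory",
    "estimate_period",
    "residence_times",
    "lyapunov_estimate",
    "ClassifySettings",
]


@dataclass(frozen=True)
class ClassifySettings:
    """Thresholds of the phenotype decision tree (lengths in um)."""

    transient_fraction: float = 0.25
    amplitude_tol: float = 1.0          # terminal spread for fixed_point
    damping_rate_tol: float = 1e-4      # envelope decay rate for damped
    peak_cv_chaos: float = 0.2          # inter-peak CV needed for chaos
    lyapunov_positive_tol: float = 1e-3 # lambda above this counts positive
    symmetric_residence_tol: float = 0.10
    symmetric_mean_tol: float = 0.10    # |mean| / amplitude
    peak_prominence: float = 1.0
    dead_band: float | None = None      # default k/4 at call time


@dataclass
class TrajectoryPhenotype:
    label: str
    period: float | None = None
    period_mad: float | None = None
    residence_fraction_dz: float = 0.0
    residence_fraction_lz: float = 0.0
    amplitude: float = 0.0
    lyapunov_estimate: float | None = None
    nested_zones: str | None = None      # 'one' | 'both' when label=='nested'
    details: dict[str, Any] = field(default_factory=dict)


def _post_transient(traj: Trajectory, fraction: float):
    n0 = int(len(traj) * fraction)
    return traj.times[n0:], traj["x"][n0:]


def estimate_period(traj: Trajectory, transient_fraction: float = 0.25,
                    prominence: float = 1.0) -> tuple[float, float]:
    """Median inter-peak interval of x(t) and its median absolute deviation.

    Requires at least 5 peaks after transient removal.
    """
    t, x = _post_transient(traj, transient_fraction)
    peaks, _ = find_peaks(x, prominence=prominence)
    if peaks.size < 5:
        raise ValueError(
            f"need >= 5 peaks to estimate a period, found {peaks.size}")
    intervals = np.diff(t[peaks])
    period = float(np.median(intervals))
    mad = float(np.median(np.abs(intervals - period)))
    return period, mad


def residence_times(traj: Trajectory, dead_band: float,
                    transient_fraction: float = 0.25) -> tuple[float, float]:
    """Fractions of post-transient time spent in each zone.

    Dark-zone side is x < -dead_band, light-zone side x > +dead_band; time
    inside the dead band counts to neither (so the fractions sum to <= 1).
    Time-weighted with the trapezoidal occupancy of each sample interval.
    """
    t, x = _post_transient(traj, transient_fraction)
    if t.size < 2:
        return 0.0, 0.0
    wt = np.empty_like(t)
    wt[0] = (t[1] - t[0]) / 2
    wt[-1] = (t[-1] - t[-2]) / 2
    wt[1:-1] = (t[2:] - t[:-2]) / 2
    total = wt.sum()
    dz = float(wt[x < -dead_band].sum() / total)
    lz = float(wt[x > +dead_band].sum() / total)
    return dz, lz


def lyapunov_estimate(model, state0, horizon: float = 6000.0,
                      renorm_dt: float = 20.0, d0: float = 1e-5,
                      transient: float = 1000.0, rtol: float = 1e-10,
                      discard_fraction: float = 0.2, seed: int = 0) -> float:
    """Largest Lyapunov exponent by two-trajectory renormalization.

    A companion trajectory offset by ``d0`` is co-integrated; every
    ``renorm_dt`` the separation is measured, its log-growth accumulated,
    and the offset rescaled back to ``d0``.  The first
    ``discard_fraction`` of the growth record is dropped so the offset can
    align with the most expanding direction.  The offset ``d0`` is kept
    well above integrator noise; estimates of a limit cycle hover near 0
    (|lambda| ~ 1e-4) rather than converging to a negative value.
    """
    rhs = model.rhs
    atol = rtol * 1e-2

    def pair_rhs(t, Y):
        n = Y.size // 2
        return np.concatenate([np.asarray(rhs(t, Y[:n])),
                               np.asarray(rhs(t, Y[n:]))])

    y = solve_ivp(rhs, (0.0, transient), np.asarray(state0, dtype=float),
                  rtol=rtol, atol=atol).y[:, -1]
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(y.size)
    u /= np.linalg.norm(u)
    z = y + d0 * u
    n_chunk = int(horizon / renorm_dt)
    logs = np.empty(n_chunk)
    for i in range(n_chunk):
        Y = solve_ivp(pair_rhs, (0.0, renorm_dt), np.concatenate([y, z]),
                      rtol=rtol, atol=atol).y[:, -1]
        y, z = Y[:y.size], Y[y.size:]
        d = np.linalg.norm(z - y)
        logs[i] = np.log(d / d0)
        z = y + (z - y) * (d0 / d)
    m = int(n_chunk * discard_fraction)
    return float(logs[m:].sum() / ((n_chunk - m) * renorm_dt))


def classify_trajectory(traj: Trajectory, env=None,
                        settings: ClassifySettings | None = None,
                        model=None, lyapunov: float | None = None
                        ) -> TrajectoryPhenotype:
    """Apply the phenotype decision tree to a displacement trace.

    ``env`` provides the zone geometry (dead band defaults to k/4); pass
    ``model`` (or a precomputed ``lyapunov``) to let the chaos branch
    confirm sensitivity to initial conditions — without either, irregular
    traces fall through to the geometric labels.
    """
    s = settings or ClassifySettings()
    t, x = _post_transient(traj, s.transient_fraction)
    if t.size < 10:
        raise ValueError("trajectory too short to classify")
    k = getattr(env, "half_separation", None) if env is not None else None
    dead_band = s.dead_band if s.dead_band is not None else (
        k / 4.0 if k else s.amplitude_tol)

    dz, lz = residence_times(traj, dead_band, s.transient_fraction)
    amplitude = float(x.max() - x.min()) / 2.0

    # 1. fixed point: terminal window has collapsed
    tail = x[int(0.9 * x.size):]
    if tail.max() - tail.min() < s.amplitude_tol:
        return TrajectoryPhenotype(
            label="fixed_point", residence_fraction_dz=dz,
            residence_fraction_lz=lz, amplitude=amplitude,
            details={"terminal_spread": float(tail.max() - tail.min()),
                     "x_final": float(tail.mean())})

    peaks, _ = find_peaks(x, prominence=s.peak_prominence)
    troughs, _ = find_peaks(-x, prominence=s.peak_prominence)

    # 2. damped: peak deviations from the final value decay exponentially
    if peaks.size >= 4:
        x_ref = float(tail.mean())
        dev = np.abs(x[peaks] - x_ref)
        if np.all(dev > 0):
            rate = np.polyfit(t[peaks], np.log(dev), 1)[0]
            first, last = dev[0], dev[-1]
            if rate < -s.damping_rate_tol and last < 0.5 * first:
                return TrajectoryPhenotype(
                    label="damped", residence_fraction_dz=dz,
                    residence_fraction_lz=lz, amplitude=amplitude,
                    details={"envelope_rate": float(rate)})

    if peaks.size < 5:
        raise ValueError(
            "trajectory too short: fewer than 5 peaks after transient")

    period, mad = estimate_period(traj, s.transient_fraction,
                                  s.peak_prominence)
    intervals = np.diff(t[peaks])
    cv = float(intervals.std() / intervals.mean())

    # 3. chaotic: irregular peak spacing AND positive Lyapunov estimate
    lam = lyapunov
    if cv > s.peak_cv_chaos and lam is None and model is not None:
        lam = lyapunov_estimate(model, traj.states[0])
    if (cv > s.peak_cv_chaos and lam is not None
            and lam > s.lyapunov_positive_tol):
        return TrajectoryPhenotype(
            label="chaotic", period=period, period_mad=mad,
            residence_fraction_dz=dz, residence_fraction_lz=lz,
            amplitude=amplitude, lyapunov_estimate=lam,
            details={"peak_cv": cv})

    # 4. intrazonal: every extremum on one side of the midline
    extrema = np.concatenate([x[peaks], x[troughs]])
    if np.all(extrema > dead_band) or np.all(extrema < -dead_band):
        return TrajectoryPhenotype(
            label="intrazonal", period=period, period_mad=mad,
            residence_fraction_dz=dz, residence_fraction_lz=lz,
            amplitude=amplitude, lyapunov_estimate=lam,
            details={"peak_cv": cv, "side": "lz" if extrema[0] > 0 else "dz"})

    # 5. nested: a loop that fails to cross the midline (local max below 0
    #    or local min above 0) rides on the large inter-zonal cycle
    small_dz = peaks.size > 0 and bool(np.any(x[peaks] < 0))
    small_lz = troughs.size > 0 and bool(np.any(x[troughs] > 0))
    if small_dz or small_lz:
        zones = "both" if (small_dz and small_lz) else "one"
        return TrajectoryPhenotype(
            label="nested", period=period, period_mad=mad,
            residence_fraction_dz=dz, residence_fraction_lz=lz,
            amplitude=amplitude, lyapunov_estimate=lam, nested_zones=zones,
            details={"peak_cv": cv})

    # 6/7. symmetric vs asymmetric inter-zonal oscillation
    mean_ok = abs(float(x.mean())) < s.symmetric_mean_tol * amplitude
    residence_ok = abs(dz - lz) < s.symmetric_residence_tol
    label = ("periodic_symmetric" if (mean_ok and residence_ok)
             else "periodic_asymmetric")
    return TrajectoryPhenotype(
        label=label, period=period, period_mad=mad,
        residence_fraction_dz=dz, residence_fraction_lz=lz,
        amplitude=amplitude, lyapunov_estimate=lam,
        details={"peak_cv": cv, "mean_x": float(x.mean())})
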