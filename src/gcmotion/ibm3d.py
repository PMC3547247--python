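"""3D individual-based simulation of migrating B cells.

Each cell carries a position, a velocity, and two surface-receptor
densities.  Per time step, a cell samples the local chemokine
concentrations and gradients from static voxel grids (trilinear
interpolation), updates its receptors with the saturable down-regulation
law, and advances its velocity with the Langevin rule

    dv = [chi (S1 + S2) - gamma v] dt + sigma dW,
    S_i = zeta r_i grad(f_i) / (1 + eps_i f_i)^2

— the 3D vector form of the 1D phenomenological model, so with sigma = 0
and a field varying along one axis a single cell reproduces the 1D ODE
trajectory up to spatial discretization error.  Cells are confined to a
box by reflective walls; an optional linear soft-sphere repulsion acts
between overlapping cells (off by default).  Each cell owns a random
generator seeded ``base_seed + cell_id``, making multi-cell runs
reproducible regardless of update order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ChemokineEnvironment, VoxelGrid3D, discretize
from .integrate import Trajectory
from .models import ReceptorParams, ChemotaxisParams, receptor_rhs
from .scenarios import Scenario, load_scenario, make_environment

__all__ = ["CellState3D", "SimulationVolume", "World", "step",
           "run_simulation", "validate_config"]

COLUMNS_3D = ("x", "y", "z", "vx", "vy", "vz", "r1", "r2")


@dataclass
class CellState3D:
    position: np.ndarray
    velocity: np.ndarray
    r1: float
    r2: float
    cell_id: int
    radius: float = 5.0


@dataclass(frozen=True)
class SimulationVolume:
    """Axis-aligned box with reflective boundaries (bounds in um)."""

    bounds: np.ndarray  # shape (3, 2)

    @classmethod
    def from_extent(cls, bounds) -> "SimulationVolume":
        b = np.asarray(bounds, dtype=float)
        if b.shape != (3, 2) or np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("volume bounds must be (3, 2) with hi > lo")
        return cls(bounds=b)

    def contains(self, positions) -> np.ndarray:
        p = np.atleast_2d(positions)
        return np.all((p >= self.bounds[:, 0]) & (p <= self.bounds[:, 1]),
                      axis=-1)

    def reflect(self, positions, velocities):
        """Mirror positions at the walls and negate the normal velocity."""
        p = positions.copy()
        v = velocities.copy()
        for _ in range(8):  # a cell cannot cross a wall many times per step
            lo_mask = p < self.bounds[:, 0]
            hi_mask = p > self.bounds[:, 1]
            if not (lo_mask.any() or hi_mask.any()):
                break
            p = np.where(lo_mask, 2 * self.bounds[:, 0] - p, p)
            p = np.where(hi_mask, 2 * self.bounds[:, 1] - p, p)
            v = np.where(lo_mask | hi_mask, -v, v)
        else:
            p = np.clip(p, self.bounds[:, 0], self.bounds[:, 1])
        return p, v


class World:
    """Mutable simulation state: cell arrays + static grids + parameters."""

    def __init__(self, grids: tuple[VoxelGrid3D, VoxelGrid3D],
                 volume: SimulationVolume, rp1: ReceptorParams,
                 rp2: ReceptorParams, cp: ChemotaxisParams,
                 positions, velocities, r1, r2, base_seed: int = 0,
                 collisions: bool = False, k_rep: float = 1.0,
                 cell_radius: float = 5.0):
        self.grid1, self.grid2 = grids
        self.volume = volume
        self.rp1, self.rp2, self.cp = rp1, rp2, cp
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
        n = self.positions.shape[0]
        self.r1 = np.broadcast_to(np.asarray(r1, dtype=float), (n,)).copy()
        self.r2 = np.broadcast_to(np.asarray(r2, dtype=float), (n,)).copy()
        self.collisions = collisions
        self.k_rep = k_rep
        self.cell_radius = cell_radius
        self.time = 0.0
        self.base_seed = base_seed
        self.rngs = [np.random.default_rng(base_seed + i) for i in range(n)]
        if not np.all(self.volume.contains(self.positions)):
            raise ValueError("all cells must start inside the volume")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def cells(self) -> list[CellState3D]:
        return [CellState3D(position=self.positions[i].copy(),
                            velocity=self.velocities[i].copy(),
                            r1=float(self.r1[i]), r2=float(self.r2[i]),
                            cell_id=i, radius=self.cell_radius)
                for i in range(self.n_cells)]


def _repulsion_forces(positions, radius, k_rep):
    """Linear soft-sphere pair forces; equal and opposite by construction."""
    n = positions.shape[0]
    F = np.zeros_like(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            dist = np.linalg.norm(d)
            overlap = 2 * radius - dist
            if overlap > 0 and dist > 1e-12:
                f = k_rep * overlap * d / dist
                F[i] += f
                F[j] -= f
    return F


def step(world: World, dt: float) -> World:
    """Advance the world by one Euler-Maruyama step of length dt."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    p, v = world.positions, world.velocities
    cp = world.cp
    F1, G1 = world.grid1.interpolate_all(p)
    F2, G2 = world.grid2.interpolate_all(p)
    F1, F2 = np.atleast_1d(F1), np.atleast_1d(F2)

    dr1 = receptor_rhs(world.r1, F1, world.rp1)
    dr2 = receptor_rhs(world.r2, F2, world.rp2)

    S1 = cp.zeta * world.r1[:, None] * G1 / (1 + cp.epsilon1 * F1[:, None]) ** 2
    S2 = cp.zeta * world.r2[:, None] * G2 / (1 + cp.epsilon2 * F2[:, None]) ** 2
    accel = cp.chi * (S1 + S2) - cp.gamma * v
    if world.collisions and world.n_cells > 1:
        accel = accel + _repulsion_forces(p, world.cell_radius, world.k_rep)

    new_p = p + dt * v
    new_v = v + dt * accel
    if cp.sigma > 0:
        noise = np.stack([world.rngs[i].standard_normal(3)
                          for i in range(world.n_cells)])
        new_v = new_v + cp.sigma * np.sqrt(dt) * noise
    new_p, new_v = world.volume.reflect(new_p, new_v)

    world.r1 = world.r1 + dt * dr1
    world.r2 = world.r2 + dt * dr2
    world.positions, world.velocities = new_p, new_v
    world.time += dt
    if not (np.all(np.isfinite(new_p)) and np.all(np.isfinite(new_v))):
        bad = np.where(~np.isfinite(new_p).all(axis=1)
                       | ~np.isfinite(new_v).all(axis=1))[0]
        raise RuntimeError(
            f"non-finite state for cell(s) {bad.tolist()} at t={world.time}")
    return world


# ---------------------------------------------------------------------------
# configured runs
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "n_cells": 1,
    "duration": 2000.0,
    "dt": 0.05,
    "save_every": 1.0,
    "seed": 0,
    "voxel_spacing": 5.0,
    "volume": None,          # default: derived from the field geometry
    "placement": "dz",       # 'dz' | 'lz' | 'center' | explicit list
    "sigma": None,            # override scenario sigma
    "collisions": False,
    "k_rep": 1.0,
    "cell_radius": 5.0,
    "initial_receptors": (1.0, 1.0),
    "initial_velocity": (1.0, 0.0, 0.0),
    "zone_axis": 0,
}


def validate_config(config: dict) -> dict:
    """Fill defaults and report all problems in one pass."""
    cfg = dict(_DEFAULT_CONFIG)
    unknown = sorted(set(config) - set(_DEFAULT_CONFIG) - {"scenario",
                                                           "model",
                                                           "parameters"})
    cfg.update({k: v for k, v in config.items() if k in _DEFAULT_CONFIG})
    errors = []
    if unknown:
        errors.append(f"unknown config keys: {unknown}")
    if "scenario" not in config and "parameters" not in config:
        errors.append("config needs 'scenario' (name/path) or 'parameters'")
    if not cfg["dt"] > 0:
        errors.append("dt must be > 0")
    if not cfg["duration"] > 0:
        errors.append("duration must be > 0")
    if int(cfg["n_cells"]) < 1:
        errors.append("n_cells must be >= 1")
    if errors:
        raise ValueError("invalid IBM config: " + "; ".join(errors))
    cfg["n_cells"] = int(cfg["n_cells"])
    cfg["seed"] = int(cfg["seed"])
    for key in ("scenario", "model", "parameters"):
        if key in config:
            cfg[key] = config[key]
    return cfg


def _initial_positions(cfg, env: ChemokineEnvironment, volume, rng):
    n = cfg["n_cells"]
    axis = cfg["zone_axis"]
    placement = cfg["placement"]
    if isinstance(placement, (list, tuple, np.ndarray)) and not isinstance(
            placement, str):
        pos = np.atleast_2d(np.asarray(placement, dtype=float))
        if pos.shape != (n, 3):
            raise ValueError("explicit placement must be (n_cells, 3)")
        return pos
    lo, hi = volume.bounds[:, 0], volume.bounds[:, 1]
    pos = rng.uniform(lo + 1.0, hi - 1.0, size=(n, 3))
    if placement == "dz":
        pos[:, axis] = env.f1.center + rng.uniform(-5, 5, size=n)
    elif placement == "lz":
        pos[:, axis] = env.f2.center + rng.uniform(-5, 5, size=n)
    elif placement == "center":
        pos[:, axis] = 0.0
    else:
        raise ValueError(f"unknown placement '{placement}'")
    return pos


def build_world(config: dict) -> tuple[World, dict]:
    """Construct a :class:`World` (plus resolved config) from a config."""
    cfg = validate_config(config)
    if "scenario" in cfg:
        sc = cfg["scenario"]
        sc = sc if isinstance(sc, Scenario) else load_scenario(sc)
        params = dict(sc.parameters)
        model_name = sc.model
    else:
        params = dict(cfg["parameters"])
        model_name = cfg.get("model", "full")
    if model_name != "full":
        raise ValueError("the IBM runs the full phenomenological model")
    if cfg["sigma"] is not None:
        params["sigma"] = float(cfg["sigma"])
    env = make_environment(params)
    spacing = float(cfg["voxel_spacing"])

    if cfg["volume"] is None:
        if cfg["zone_axis"] != 0:
            raise ValueError("give explicit 'volume' bounds when the zone "
                             "axis is not x")
        k, w = params["k"], params["w"]
        half = k + 3 * w
        vol_bounds = np.array([[-half, half], [-60.0, 60.0], [-60.0, 60.0]])
    else:
        vol_bounds = np.asarray(cfg["volume"], dtype=float)
    volume = SimulationVolume.from_extent(vol_bounds)
    # pad the grid so the centroid hull covers the whole volume
    grid_bounds = vol_bounds + np.array([-2.0, 2.0]) * spacing
    g1, g2 = discretize(env, grid_bounds, spacing=spacing,
                        axis=cfg["zone_axis"])

    rp1 = ReceptorParams(pi=params["pi1"], tau=params["tau1"],
                         kappa=params["kappa1"], delta=params["delta1"])
    rp2 = ReceptorParams(pi=params["pi2"], tau=params["tau2"],
                         kappa=params["kappa2"], delta=params["delta2"])
    cp = ChemotaxisParams(chi=params["chi"], epsilon1=params["epsilon1"],
                          epsilon2=params["epsilon2"], gamma=params["gamma"],
                          zeta=params.get("zeta", 1.0),
                          sigma=params.get("sigma", 0.0))

    rng = np.random.default_rng(cfg["seed"])
    pos = _initial_positions(cfg, env, volume, rng)
    vel = np.tile(np.asarray(cfg["initial_velocity"], dtype=float),
                  (cfg["n_cells"], 1))
    r1_0, r2_0 = cfg["initial_receptors"]
    world = World((g1, g2), volume, rp1, rp2, cp, pos, vel, r1_0, r2_0,
                  base_seed=cfg["seed"], collisions=cfg["collisions"],
                  k_rep=cfg["k_rep"], cell_radius=cfg["cell_radius"])
    cfg_resolved = dict(cfg)
    cfg_resolved["parameters"] = params
    return world, cfg_resolved


def run_simulation(config: dict) -> list[Trajectory]:
    """Run a configured multi-cell simulation; one Trajectory per cell."""
    world, cfg = build_world(config)
    dt = float(cfg["dt"])
    n_steps = int(round(cfg["duration"] / dt))
    stride = max(1, int(round(cfg["save_every"] / dt)))
    times = [0.0]
    snaps = [_snapshot(world)]
    for i in range(n_steps):
        step(world, dt)
        if (i + 1) % stride == 0 or i == n_steps - 1:
            times.append(world.time)
            snaps.append(_snapshot(world))
    times = np.asarray(times)
    data = np.stack(snaps)  # (T, n_cells, 8)
    out = []
    for c in range(world.n_cells):
        meta = {"model": "ibm3d", "cell_id": c, "seed": cfg["seed"],
                "dt": dt, "sigma": world.cp.sigma,
                "parameters": cfg["parameters"]}
        out.append(Trajectory(times=times, states=data[:, c, :],
                              columns=COLUMNS_3D, meta=meta))
    return out


def _snapshot(world: World) -> np.ndarray:
    return np.concatenate(
        [world.positions, world.velocities,
         world.r1[:, None], world.r2[:, None]], axis=1)
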