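"""Static chemokine fields.

The germinal-center environment is modelled as two fixed Gaussian chemokine
profiles along the dark-zone/light-zone axis: CXCL12 (bound by CXCR4) centred
at ``-k`` and CXCL13 (bound by CXCR5) centred at ``+k``, where ``k`` is the
half-distance between the zone centroids in micrometres.  Each profile is an
unnormalized peak-height Gaussian

    f(x) = c * exp(-(x - centre)^2 / (2 w^2))

so ``c`` is the concentration at the peak and ``w`` the width.  Fields are
functions of the *cell displacement* x: a migrating cell samples the local
concentration and gradient at its own position.

For the 3D individual-based simulator the analytic 1D environment is
discretized onto a voxel grid (default 5 um voxels) with trilinear
interpolation between voxel centroids, which generalizes to arbitrary
measured or evolving chemokine maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianField1D",
    "ChemokineEnvironment",
    "VoxelGrid3D",
    "discretize",
]


@dataclass(frozen=True)
class GaussianField1D:
    """Unnormalized Gaussian concentration profile.

    Parameters
    ----------
    height : float
        Peak concentration ``c`` (arbitrary concentration units, > 0).
    width : float
        Gaussian width ``w`` in um (> 0).
    center : float
        Peak position in um (signed).
    """

    height: float
    width: float
    center: float = 0.0

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")

    def value(self, x):
        """Concentration at displacement ``x``: c*exp(-(x-mu)^2/(2w^2))."""
        x = np.asarray(x, dtype=float)
        return self.height * np.exp(-((x - self.center) ** 2) / (2.0 * self.width**2))

    def gradient(self, x):
        """Exact analytic spatial derivative of :meth:`value`."""
        x = np.asarray(x, dtype=float)
        return -((x - self.center) / self.width**2) * self.value(x)

    def second_derivative(self, x):
        """Exact analytic d2f/dx2 (used by analytic Jacobians)."""
        x = np.asarray(x, dtype=float)
        u = (x - self.center) / self.width**2
        return (u * u - 1.0 / self.width**2) * self.value(x)

    def __call__(self, x):
        return self.value(x)


@dataclass(frozen=True)
class ChemokineEnvironment:
    """Two opposing chemokine fields on the zone axis.

    ``f1`` is the CXCL12 profile (dark/light-zone convention: centred at
    ``-k``) and ``f2`` the CXCL13 profile centred at ``+k``.  Constructed
    either from two explicit :class:`GaussianField1D` or via
    :meth:`symmetric`.
    """

    f1: GaussianField1D
    f2: GaussianField1D
    half_separation: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.half_separation < 0:
            raise ValueError("half_separation must be >= 0")

    @classmethod
    def symmetric(cls, c: float, w: float, k: float,
                  c2: float | None = None, w2: float | None = None
                  ) -> "ChemokineEnvironment":
        """Environment with centres at -k (f1) and +k (f2).

        ``c2``/``w2`` default to ``c``/``w`` (identical profiles).
        """
        f1 = GaussianField1D(height=c, width=w, center=-k)
        f2 = GaussianField1D(height=c2 if c2 is not None else c,
                             width=w2 if w2 is not None else w, center=+k)
        return cls(f1=f1, f2=f2, half_separation=k)

    def values(self, x):
        return self.f1.value(x), self.f2.value(x)

    def gradients(self, x):
        return self.f1.gradient(x), self.f2.gradient(x)


class VoxelGrid3D:
    """Regular 3D voxel grid of concentrations with trilinear interpolation.

    Voxel centroid ``(i, j, l)`` sits at ``origin + (i+0.5, j+0.5, l+0.5) *
    spacing``.  Values are interpolated trilinearly between the 8 centroids
    surrounding a query point; gradients are precomputed per-axis central
    differences at centroids (one-sided at the boundary) and interpolated
    with the same trilinear weights, which keeps the gradient continuous.
    """

    def __init__(self, origin, spacing: float, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not spacing > 0:
            raise ValueError("spacing must be > 0")
        if np.any(values < 0):
            raise ValueError("concentrations must be >= 0")
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.values = values
        self.shape = values.shape
        self._grad = np.stack(np.gradient(values, spacing), axis=0)

    # centroid coordinates of voxel index along one axis
    def centroid(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def _locate(self, p):
        """Fractional index of p in centroid space; errors outside hull.

        Accepts a single point (3,) or a batch (..., 3).
        """
        p = np.asarray(p, dtype=float)
        g = (p - self.origin) / self.spacing - 0.5
        hi = np.array(self.shape) - 1
        if np.any(g < -1e-9) or np.any(g > hi + 1e-9):
            raise ValueError(
                f"query outside the grid's centroid hull (indices 0..{hi})")
        g = np.clip(g, 0.0, hi)
        i0 = np.minimum(g.astype(int), np.maximum(hi - 1, 0))
        t = g - i0
        return i0, t

    def _blend(self, arr, i0, t):
        """Corner-weighted sum; arr has the grid as its last three axes."""
        out = 0.0
        for di in (0, 1):
            wx = t[..., 0] if di else 1.0 - t[..., 0]
            for dj in (0, 1):
                wy = t[..., 1] if dj else 1.0 - t[..., 1]
                for dl in (0, 1):
                    wz = t[..., 2] if dl else 1.0 - t[..., 2]
                    # clamp handles degenerate single-voxel axes
                    ii = np.minimum(i0[..., 0] + di, self.shape[0] - 1)
                    jj = np.minimum(i0[..., 1] + dj, self.shape[1] - 1)
                    ll = np.minimum(i0[..., 2] + dl, self.shape[2] - 1)
                    out = out + wx * wy * wz * arr[..., ii, jj, ll]
        return out

    def interpolate(self, p):
        """Trilinearly interpolated concentration at point(s) ``p`` (um)."""
        i0, t = self._locate(p)
        out = self._blend(self.values, i0, t)
        return float(out) if np.ndim(out) == 0 else out

    def interpolate_gradient(self, p) -> np.ndarray:
        """Interpolated concentration gradient; (..., 3) for batched p."""
        i0, t = self._locate(p)
        comps = [self._blend(self._grad[a], i0, t) for a in range(3)]
        return np.stack(np.broadcast_arrays(*comps), axis=-1).astype(float)

    def interpolate_all(self, p):
        """Value and gradient in one pass: (value, gradient(..., 3))."""
        if not hasattr(self, "_stacked"):
            self._stacked = np.concatenate([self.values[None], self._grad],
                                           axis=0)
        i0, t = self._locate(p)
        out = self._blend(self._stacked, i0, t)  # (4, ...)
        return out[0], np.moveaxis(out[1:], 0, -1)


def discretize(env: ChemokineEnvironment, bounds, spacing: float = 5.0,
               axis: int = 0) -> tuple[VoxelGrid3D, VoxelGrid3D]:
    """Sample a 1D environment onto two 3D voxel grids (one per chemokine).

    Parameters
    ----------
    env : ChemokineEnvironment
    bounds : array-like, shape (3, 2)
        ``[[xmin, xmax], [ymin, ymax], [zmin, zmax]]`` in um.  Must contain
        both field centres along ``axis``.
    spacing : float
        Voxel edge length in um (default 5, matching the simulator).
    axis : int
        The zone axis along which the 1D profiles vary; the fields are
        constant in the two remaining directions.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (3, 2):
        raise ValueError("bounds must have shape (3, 2)")
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    lo, hi = bounds[axis]
    for f in (env.f1, env.f2):
        if not (lo <= f.center <= hi):
            raise ValueError(
                f"bounds [{lo}, {hi}] along axis {axis} exclude field centre "
                f"{f.center}")
    n = np.maximum(np.ceil((bounds[:, 1] - bounds[:, 0]) / spacing), 1).astype(int)
    origin = bounds[:, 0]
    coords = origin[axis] + (np.arange(n[axis]) + 0.5) * spacing
    grids = []
    for f in (env.f1, env.f2):
        line = f.value(coords)
        vals = np.ones(n)
        sl = [None, None, None]
        sl[axis] = slice(None)
        vals = vals * line[tuple(sl)]
        grids.append(VoxelGrid3D(origin=origin, spacing=spacing, values=vals))
    return grids[0], grids[1]
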