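"""Monolayer state containers and initialization.

Each cell carries a full 3D phase field ``phi`` (1 inside, 0 outside, tanh
interface of width ``lam``), an in-plane polarity angle ``theta``, and the
latest centroid / velocity / traction diagnostics.  The substrate is a static
phase field occupying ``z < z_wall``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .params import ModelParams

__all__ = ["CellState", "MonolayerState", "init_monolayer", "wall_field", "tanh_sphere"]


@dataclass
class CellState:
    phi: np.ndarray              # (nx, ny, nz) phase field
    theta: float                 # polarity angle in [-pi, pi]
    centroid: np.ndarray         # unwrapped 3-vector (continuous across PBC)
    velocity: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    traction: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    @property
    def polarity(self) -> np.ndarray:
        """In-plane polarity unit vector (cos theta, sin theta, 0)."""
        return np.array([math.cos(self.theta), math.sin(self.theta), 0.0])

    def volume(self, a0: float = 1.0) -> float:
        """Phase-field volume integral of phi^2."""
        return float(np.sum(self.phi**2)) * a0**3


@dataclass
class MonolayerState:
    cells: list[CellState]
    wall: np.ndarray             # static substrate field phi_w
    time: int = 0                # elapsed steps
    clamp_events: int = 0        # cumulative out-of-[0,1] clamps
    low_volume_flags: list[int] = dc_field(default_factory=list)

    @property
    def N(self) -> int:
        return len(self.cells)

    def phi_stack(self) -> np.ndarray:
        """All cell fields stacked to shape (N, nx, ny, nz)."""
        return np.stack([c.phi for c in self.cells])

    def centroids(self, box: tuple[float, float] | None = None) -> np.ndarray:
        """(N, 3) centroids; wrapped into the periodic box when given."""
        x = np.array([c.centroid for c in self.cells])
        if box is not None:
            x[:, 0] %= box[0]
            x[:, 1] %= box[1]
        return x

    def copy(self) -> "MonolayerState":
        return MonolayerState(
            cells=[CellState(c.phi.copy(), c.theta, c.centroid.copy(),
                             c.velocity.copy(), c.traction.copy())
                   for c in self.cells],
            wall=self.wall,  # static by contract: shared, never mutated
            time=self.time,
            clamp_events=self.clamp_events,
            low_volume_flags=list(self.low_volume_flags),
        )


def wall_field(params: ModelParams) -> np.ndarray:
    """Static substrate field: tanh profile occupying z < z_wall."""
    nx, ny, nz = params.grid
    z = np.arange(nz, dtype=float) * params.a0
    prof = 0.5 * (1.0 - np.tanh(2.0 * (z - params.z_wall) / params.lam))
    return np.broadcast_to(prof.astype(params.np_dtype), (nx, ny, nz)).copy()


def tanh_sphere(center: np.ndarray, radius: float, params: ModelParams) -> np.ndarray:
    """Smoothed spherical indicator with interface width lam.

    The tanh radius is inflated by lam/4 so the phase-field volume
    ``int phi^2`` matches (4/3) pi radius^3 to leading order in lam/radius
    (the interface deficit of phi^2 is lam/4 per unit area).
    """
    nx, ny, nz = params.grid
    a0 = params.a0
    x = np.arange(nx, dtype=float)[:, None, None] * a0
    y = np.arange(ny, dtype=float)[None, :, None] * a0
    z = np.arange(nz, dtype=float)[None, None, :] * a0
    dx = x - center[0]
    dy = y - center[1]
    # minimum image in the periodic plane
    Lx, Ly = nx * a0, ny * a0
    dx -= Lx * np.round(dx / Lx)
    dy -= Ly * np.round(dy / Ly)
    dz = z - center[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    r_eff = radius + params.lam / 4.0
    phi = 0.5 * (1.0 + np.tanh(2.0 * (r_eff - r) / params.lam))
    return phi.astype(params.np_dtype)


def _packing_positions(params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Jittered near-triangular packing of N in-plane seed positions."""
    N = params.N
    nx, ny, nz = params.grid
    Lx, Ly = nx * params.a0, ny * params.a0
    # choose the rows x cols factorization closest to a triangular packing
    # (row spacing sqrt(3)/2 of the column spacing)
    best = None
    for rows_try in range(1, N + 1):
        if N % rows_try:
            continue
        cols_try = N // rows_try
        cost = abs(Lx / cols_try - (Ly / rows_try) * 2.0 / math.sqrt(3.0))
        if best is None or cost < best[0]:
            best = (cost, rows_try, cols_try)
    _, rows, cols = best
    sx, sy = Lx / cols, Ly / rows
    if min(sx, sy) <= params.R0:
        need = math.ceil(params.R0 * max(cols, rows) + 1)
        raise ValueError(
            f"box {Lx:g}x{Ly:g} too small for N={N} cells of radius R0={params.R0}: "
            f"in-plane spacing {min(sx, sy):.2f} <= R0; need at least ~{need}x{need}"
        )
    jitter = 0.05 * min(sx, sy)
    # seed slightly above the substrate so the two diffuse interfaces do not
    # start deeply overlapped (adhesion pulls the layer down during relaxation)
    z0 = params.z_wall + params.R0 + params.lam / 2.0
    pos = np.empty((N, 3))
    k = 0
    for iy in range(rows):
        for ix in range(cols):
            px = (ix + 0.5 + 0.5 * (iy % 2)) * sx
            py = (iy + 0.5) * sy
            pos[k] = (
                (px + rng.uniform(-jitter, jitter)) % Lx,
                (py + rng.uniform(-jitter, jitter)) % Ly,
                z0,
            )
            k += 1
    return pos


def init_monolayer(params: ModelParams,
                   rng: np.random.Generator | None = None) -> MonolayerState:
    """Build the initial confluent monolayer.

    Cells are tanh spheres of radius R0 centered on a jittered near-triangular
    packing sitting on the substrate; polarity angles are drawn uniformly on
    [-pi, pi] from the seeded RNG.  Deterministic given (params, seed).
    """
    params.check()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    positions = _packing_positions(params, rng)
    thetas = rng.uniform(-math.pi, math.pi, size=params.N)
    wall = wall_field(params)
    cells = [
        CellState(
            phi=tanh_sphere(positions[i], params.R0, params),
            theta=float(thetas[i]),
            centroid=positions[i].copy(),
        )
        for i in range(params.N)
    ]
    return MonolayerState(cells=cells, wall=wall)
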