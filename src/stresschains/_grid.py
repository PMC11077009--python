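"""Finite-difference operators on the simulation lattice.

Fields have shape ``(..., nx, ny, nz)``.  Boundary conditions follow the
monolayer geometry: periodic in x and y (the substrate plane), zero-flux
(Neumann) at the bottom and top z boundaries.  All stencils are second-order
central differences except the upwind advection derivative.
"""

from __future__ import annotations

import numpy as np

AX_X, AX_Y, AX_Z = -3, -2, -1


def _shift_z(f: np.ndarray, step: int) -> np.ndarray:
    """Shift along z with edge replication (zero-flux)."""
    out = np.empty_like(f)
    if step == 1:  # out[..., k] = f[..., k+1]
        out[..., :-1] = f[..., 1:]
        out[..., -1] = f[..., -1]
    elif step == -1:
        out[..., 1:] = f[..., :-1]
        out[..., 0] = f[..., 0]
    else:
        raise ValueError("step must be +-1")
    return out


def laplacian(f: np.ndarray, a0: float = 1.0) -> np.ndarray:
    """7-point Laplacian, periodic in x/y, Neumann in z."""
    lap = (
        np.roll(f, 1, AX_X) + np.roll(f, -1, AX_X)
        + np.roll(f, 1, AX_Y) + np.roll(f, -1, AX_Y)
        + _shift_z(f, 1) + _shift_z(f, -1)
        - 6.0 * f
    )
    return lap / (a0 * a0)


def gradient(f: np.ndarray, a0: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference gradient (gx, gy, gz)."""
    inv2 = 0.5 / a0
    gx = (np.roll(f, -1, AX_X) - np.roll(f, 1, AX_X)) * inv2
    gy = (np.roll(f, -1, AX_Y) - np.roll(f, 1, AX_Y)) * inv2
    gz = (_shift_z(f, 1) - _shift_z(f, -1)) * inv2
    return gx, gy, gz


def face_differences(f: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward differences on lattice faces (periodic x/y, interior z faces).

    The discrete energy sum of squared face differences has exactly the
    7-point ``laplacian`` (with replicated z edges) as its variation, which
    keeps the discrete free energy and the discrete functional derivative
    consistent to machine precision.
    """
    dx = np.roll(f, -1, AX_X) - f
    dy = np.roll(f, -1, AX_Y) - f
    dz = f[..., 1:] - f[..., :-1]
    return dx, dy, dz


def face_grad_dot(f: np.ndarray, g: np.ndarray, a0: float = 1.0) -> float:
    """Discrete integral of grad(f) . grad(g) via face differences.

    Sums over trailing (x, y, z) axes; leading axes are summed too.
    """
    fx, fy, fz = face_differences(f)
    gx, gy, gz = face_differences(g)
    s = float(np.sum(fx * gx) + np.sum(fy * gy) + np.sum(fz * gz))
    return s * a0  # (1/a0^2) * a0^3


def upwind_advection(f: np.ndarray, v: np.ndarray, a0: float = 1.0) -> np.ndarray:
    """First-order upwind v . grad(f) for a constant advection velocity ``v``.

    ``v`` is a 3-vector (the cell's rigid-body velocity); upwinding picks the
    one-sided difference against the flow direction, which keeps the scheme
    stable under the CFL bound.
    """
    out = np.zeros_like(f)
    inv = 1.0 / a0
    vx, vy, vz = float(v[0]), float(v[1]), float(v[2])
    if vx > 0:
        out += vx * (f - np.roll(f, 1, AX_X)) * inv
    elif vx < 0:
        out += vx * (np.roll(f, -1, AX_X) - f) * inv
    if vy > 0:
        out += vy * (f - np.roll(f, 1, AX_Y)) * inv
    elif vy < 0:
        out += vy * (np.roll(f, -1, AX_Y) - f) * inv
    if vz > 0:
        out += vz * (f - _shift_z(f, -1)) * inv
    elif vz < 0:
        out += vz * (_shift_z(f, 1) - f) * inv
    return out
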