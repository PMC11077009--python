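"""Coarse-grained stress fields and their scalar reductions.

The per-node traction field collects, for every lattice node, each cell's
passive traction density (dF/dphi_i) grad phi_i plus its active force density
(alpha p_i weighted by phi_i^2 and normalized so the cell integral recovers
alpha p_i exactly).  The stress tensor on the complementary (dual) lattice is

    sigma_i = (1/a0^3) sum_{j in N_i} r_ij (x) T_j,

with N_i the 8 corner nodes of the dual cell (so out-of-plane components are
resolved) and the z-column summed to produce the 2D analysis field; the
purely in-plane 4-node stencil is retained as an option.  The dyadic product
is symmetrized on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._grid import gradient
from .energy import functional_derivative_stack
from .fields import ScalarField2D, TensorField2D
from .monolayer import MonolayerState
from .params import ModelParams

__all__ = [
    "TractionField",
    "nodal_traction_field",
    "coarse_grained_stress",
    "time_average",
    "isotropic_stress",
    "out_of_plane_stress",
    "max_inplane_shear",
    "susceptibility",
    "field_statistics_sweep",
]


@dataclass
class TractionField:
    """Force per node of the original 3D lattice, shape (3, nx, ny, nz)."""

    values: np.ndarray
    spacing: float = 1.0

    def total(self) -> np.ndarray:
        """Sum over all nodes: recovers sum_i (T_i + F_i^act)."""
        return self.values.sum(axis=(1, 2, 3))


def nodal_traction_field(state: MonolayerState, params: ModelParams) -> TractionField:
    """Per-node traction (active + passive), partitioning the cell totals."""
    if state.wall.shape != tuple(params.grid):
        raise ValueError(
            f"state grid {state.wall.shape} does not match params.grid {tuple(params.grid)}"
        )
    a0 = params.a0
    dV = a0**3
    out = np.zeros((3,) + tuple(params.grid))
    if state.N == 0:
        return TractionField(out, a0)
    phi = state.phi_stack()
    dF = functional_derivative_stack(state, params)
    gx, gy, gz = gradient(phi, a0)
    # passive density, summed over cells
    out[0] = (dF * gx).sum(axis=0) * dV
    out[1] = (dF * gy).sum(axis=0) * dV
    out[2] = (dF * gz).sum(axis=0) * dV
    # active density: alpha * p_i distributed proportionally to phi_i^2
    if params.alpha != 0.0:
        phi2 = phi**2
        weights = phi2 / phi2.sum(axis=(1, 2, 3), keepdims=True)
        for i, cell in enumerate(state.cells):
            p = params.alpha * np.array(
                [math.cos(cell.theta), math.sin(cell.theta), 0.0])
            for a in range(3):
                out[a] += p[a] * weights[i]
    return TractionField(out, a0)


def coarse_grained_stress(traction: TractionField,
                          stencil: str = "dual8") -> TensorField2D:
    """Eq.-style dyadic coarse-graining onto the 2D dual lattice.

    ``dual8``: complementary nodes at (i+1/2, j+1/2, k+1/2), neighbours the 8
    corner nodes, z-column summed.  ``face4``: in-plane dual nodes with the 4
    facially adjacent nodes of each z-layer (out-of-plane components vanish
    identically).  Periodic wrap in x and y.
    """
    T = np.asarray(traction.values, dtype=float)
    a0 = traction.spacing
    _, nx, ny, nz = T.shape
    sig = np.zeros((3, 3, nx, ny))

    if stencil == "dual8":
        # z-sums of the two z-windows entering dual layers k=0..nz-2
        zsum0 = T[:, :, :, :-1].sum(axis=3)   # corners at dz=0
        zsum1 = T[:, :, :, 1:].sum(axis=3)    # corners at dz=1
        for dx in (0, 1):
            for dy in (0, 1):
                for dz, zs in ((0, zsum0), (1, zsum1)):
                    r = (0.5 - dx, 0.5 - dy, 0.5 - dz)
                    for b in range(3):
                        shifted = np.roll(np.roll(zs[b], -dx, 0), -dy, 1)
                        for a in range(3):
                            if r[a]:
                                sig[a, b] += r[a] * a0 * shifted
    elif stencil == "face4":
        zsum = T.sum(axis=3)
        for dx in (0, 1):
            for dy in (0, 1):
                r = (0.5 - dx, 0.5 - dy, 0.0)
                for b in range(3):
                    shifted = np.roll(np.roll(zsum[b], -dx, 0), -dy, 1)
                    for a in range(2):
                        sig[a, b] += r[a] * a0 * shifted
    else:
        raise ValueError(f"unknown stencil {stencil!r} (use 'dual8' or 'face4')")

    sig /= a0**3
    sym = 0.5 * (sig + sig.transpose(1, 0, 2, 3))
    comps = np.stack([sym[0, 0], sym[1, 1], sym[2, 2],
                      sym[0, 1], sym[0, 2], sym[1, 2]])
    return TensorField2D(components=comps, spacing=a0, n_frames_averaged=1)


def time_average(frames) -> TensorField2D:
    """Arithmetic mean of congruent tensor frames."""
    frames = list(frames)
    if not frames:
        raise ValueError("time_average requires at least one frame")
    shape = frames[0].shape
    for f in frames:
        if f.shape != shape:
            raise ValueError("frames have mismatched lattice shapes")
    comps = np.mean([f.components for f in frames], axis=0)
    return TensorField2D(components=comps, spacing=frames[0].spacing,
                         n_frames_averaged=sum(f.n_frames_averaged for f in frames))


def _normalize(values: np.ndarray, convention: str) -> float:
    if convention == "compression":
        # maximum compression = deepest negative value (sign preserved in field)
        vmin = values.min()
        denom = -vmin if vmin < 0 else float(np.abs(values).max())
    elif convention == "abs":
        denom = float(np.abs(values).max())
    elif convention == "max":
        denom = float(values.max())
    else:
        raise ValueError(f"unknown normalization convention {convention!r}")
    if denom == 0.0:
        raise ValueError("cannot normalize an identically-zero field")
    return float(denom)


def isotropic_stress(field: TensorField2D, normalize: bool = False,
                     convention: str = "compression") -> ScalarField2D:
    """(1/3) trace per node; optionally normalized (default: by maximum
    compression, sign preserved)."""
    iso = (field.comp("xx") + field.comp("yy") + field.comp("zz")) / 3.0
    norm = None
    if normalize:
        norm = _normalize(iso, convention)
        iso = iso / norm
    return ScalarField2D(values=iso, spacing=field.spacing, kind="iso",
                         normalization=norm)


def out_of_plane_stress(field: TensorField2D, normalize: bool = False) -> ScalarField2D:
    """zz component; normalized variant divides by its maximum magnitude."""
    zz = field.comp("zz").copy()
    norm = None
    if normalize:
        norm = _normalize(zz, "abs")
        zz /= norm
    return ScalarField2D(values=zz, spacing=field.spacing, kind="zz",
                         normalization=norm)


def max_inplane_shear(field: TensorField2D, normalize: bool = False) -> ScalarField2D:
    """Half the in-plane principal stress difference,
    sqrt(((sxx - syy)/2)^2 + sxy^2) — invariant under in-plane rotation."""
    tau = np.sqrt(((field.comp("xx") - field.comp("yy")) / 2.0) ** 2
                  + field.comp("xy") ** 2)
    norm = None
    if normalize:
        norm = _normalize(tau, "abs")
        tau = tau / norm
    return ScalarField2D(values=tau, spacing=field.spacing, kind="tau",
                         normalization=norm)


def susceptibility(field: ScalarField2D | np.ndarray) -> float:
    """Extensive fluctuation measure chi = n (<x^2> - <x>^2), n = site count."""
    v = field.values if isinstance(field, ScalarField2D) else np.asarray(field)
    if v.size == 0:
        raise ValueError("susceptibility of an empty field")
    return float(v.size * (np.mean(v**2) - np.mean(v) ** 2))


def field_statistics_sweep(fields: dict[float, ScalarField2D],
                           reference: float) -> pd.DataFrame:
    """Mean and susceptibility versus control value, normalized at a
    reference control point; rows sorted by (strictly increasing) control."""
    if reference not in fields:
        raise ValueError(f"reference control value {reference} not in sweep")
    controls = sorted(fields)
    means = np.array([float(np.mean(fields[c].values)) for c in controls])
    chis = np.array([susceptibility(fields[c]) for c in controls])
    i_ref = controls.index(reference)
    return pd.DataFrame({
        "control": controls,
        "mean": means,
        "chi": chis,
        "mean_norm": means / means[i_ref],
        "chi_norm": chis / chis[i_ref],
    })
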