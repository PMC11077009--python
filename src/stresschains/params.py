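"""Model parameters for the multi-phase-field monolayer.

All quantities are expressed in lattice units: the lattice spacing ``a0`` is
the unit of length and the phase-field mobility sets the unit of time through
the relaxational dynamics.  The two dimensionless drives of the model are

* ``omega_tilde = omega_cc / omega_cw`` — cell–cell to cell–substrate
  adhesion ratio, and
* ``alpha_tilde = alpha * tau_pol / (xi_fric * R0)`` — dimensionless active
  traction strength,

which are the two independent control parameters steering the monolayer
between solid-like and liquid-like states.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

__all__ = ["ModelParams"]


@dataclass
class ModelParams:
    """Physical and numerical parameters of the monolayer model.

    Defaults are calibrated only to produce a stable confluent layer at
    desk scale; every value can be overridden from a YAML config.
    """

    # --- geometry / population ---
    N: int = 16
    R0: float = 8.0
    grid: Tuple[int, int, int] = (64, 64, 24)
    a0: float = 1.0
    z_wall: float = 3.0

    # --- free-energy coefficients ---
    E: float = 0.08            # cell stiffness (sets interface tension scale)
    mu: float = 2000.0         # volume-constraint strength (scales with cell volume)
    lam: float = 2.0           # diffuse-interface width
    kappa_cc: float = 0.02     # cell-cell repulsion
    kappa_cw: float = 0.5      # cell-substrate repulsion
    omega_cc: float = 0.002    # cell-cell adhesion
    omega_cw: float = 0.02     # cell-substrate adhesion

    # --- dynamics ---
    Gamma: float = 1.0         # phase-field mobility
    xi_fric: float = 5.0       # substrate friction
    alpha: float = 0.0         # self-propulsion strength
    tau_pol: float = 4.0       # polarity alignment time
    Dr: float = 0.6        # rotational noise amplitude (literal, not 2Dr)

    # --- numerics ---
    dt: float = 0.03
    n_sim: int = 0             # number of recorded steps
    seed: int = 0
    cfl_max: float = 0.4       # abort threshold on max|v|*dt/a0
    dtype: str = "float64"     # field precision ("float32" speeds desk runs)

    # Explicit prefactor overrides for the three interaction families; None
    # means the default convention c_bulk=E*lam/2, c_rep=kappa/lam,
    # c_adh=omega*lam^2 (the typography of the underlying free energy admits
    # more than one reading, so the coefficients stay configurable).
    c_bulk: float | None = None
    c_rep_cc: float | None = None
    c_rep_cw: float | None = None
    c_adh_cc: float | None = None
    c_adh_cw: float | None = None

    # ------------------------------------------------------------------
    @property
    def np_dtype(self):
        import numpy as np
        return np.dtype(self.dtype)

    @property
    def V0(self) -> float:
        """Target cell volume (4/3) pi R0^3."""
        return 4.0 / 3.0 * math.pi * self.R0**3

    @property
    def omega_tilde(self) -> float:
        """Dimensionless cell–cell to cell–substrate adhesion ratio."""
        return self.omega_cc / self.omega_cw

    @property
    def alpha_tilde(self) -> float:
        """Dimensionless active traction strength alpha*tau_pol/(xi*R0)."""
        return self.alpha * self.tau_pol / (self.xi_fric * self.R0)

    # effective coefficients -------------------------------------------
    @property
    def coef_bulk(self) -> float:
        return self.E * self.lam / 2.0 if self.c_bulk is None else self.c_bulk

    @property
    def coef_rep_cc(self) -> float:
        return self.kappa_cc / self.lam if self.c_rep_cc is None else self.c_rep_cc

    @property
    def coef_rep_cw(self) -> float:
        return self.kappa_cw / self.lam if self.c_rep_cw is None else self.c_rep_cw

    @property
    def coef_adh_cc(self) -> float:
        return self.omega_cc * self.lam**2 if self.c_adh_cc is None else self.c_adh_cc

    @property
    def coef_adh_cw(self) -> float:
        return self.omega_cw * self.lam**2 if self.c_adh_cw is None else self.c_adh_cw

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        v: list[str] = []
        for name in ("E", "mu", "Gamma", "xi_fric", "tau_pol", "lam"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be strictly positive")
        for name in ("alpha", "Dr", "kappa_cc", "kappa_cw", "omega_cc", "omega_cw"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be non-negative")
        if self.lam < 2 * self.a0:
            v.append(
                f"lam={self.lam} < 2*a0={2 * self.a0}: diffuse interface is not "
                "resolved on the lattice (interface-resolution rule)"
            )
        if self.R0 < 4 * self.a0:
            v.append(f"R0={self.R0} must be well above the lattice spacing a0={self.a0}")
        if self.N < 1:
            v.append("N must be >= 1")
        if self.dt <= 0:
            v.append("dt must be positive")
        if self.dtype not in ("float32", "float64"):
            v.append(f"dtype must be float32 or float64, got {self.dtype}")
        if len(self.grid) != 3 or any(g < 4 for g in self.grid):
            v.append("grid must be three extents, each >= 4")
        else:
            need_z = self.z_wall + 2.0 * self.R0 + 2.0 * self.lam
            if self.grid[2] * self.a0 < need_z:
                v.append(
                    f"grid z-extent {self.grid[2] * self.a0:g} too short: a cell "
                    f"seeded on the substrate needs headroom >= z_wall + 2 R0 "
                    f"+ 2 lam = {need_z:g} or it interacts with the top boundary"
                )
        if self.omega_cw > 0 and not math.isfinite(self.omega_tilde):
            v.append("omega_tilde must be finite")
        return v

    def check(self) -> "ModelParams":
        """Raise ``ValueError`` on the first invariant violation."""
        v = self.validate()
        if v:
            raise ValueError("invalid ModelParams: " + "; ".join(v))
        return self

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        d = dict(d)
        if "grid" in d:
            d["grid"] = tuple(d["grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_drives(self, omega_tilde: float | None = None,
                    alpha_tilde: float | None = None) -> "ModelParams":
        """Copy with omega_cc / alpha set from the dimensionless drives."""
        p = dataclasses.replace(self)
        if omega_tilde is not None:
            p.omega_cc = omega_tilde * p.omega_cw
        if alpha_tilde is not None:
            p.alpha = alpha_tilde * p.xi_fric * p.R0 / p.tau_pol
        return p
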