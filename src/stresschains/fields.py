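"""Lattice field containers for the 2D stress analysis plane.

``TensorField2D`` stores the symmetrized coarse-grained stress tensor per
node of the complementary (dual) lattice, in 6-component symmetric storage
(xx, yy, zz, xy, xz, yz).  ``ScalarField2D`` carries derived scalars
(isotropic stress, out-of-plane stress, maximum in-plane shear, or any
synthetic field) plus the normalization used, when one was applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ScalarField2D", "TensorField2D", "SYM_COMPONENTS"]

SYM_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class ScalarField2D:
    values: np.ndarray                 # (nx, ny)
    spacing: float = 1.0
    kind: str = "other"                # one of {iso, zz, tau, other}
    normalization: float | None = None  # divisor applied, if normalized
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarField2D requires a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path, values=self.values, spacing=self.spacing, kind=self.kind,
            normalization=np.nan if self.normalization is None else self.normalization,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScalarField2D":
        with np.load(path, allow_pickle=False) as z:
            norm = float(z["normalization"])
            return cls(
                values=z["values"], spacing=float(z["spacing"]),
                kind=str(z["kind"]),
                normalization=None if np.isnan(norm) else norm,
            )

    def to_csv(self, path: str | Path) -> None:
        nx, ny = self.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        pd.DataFrame(
            {"i": ii.ravel(), "j": jj.ravel(), "value": self.values.ravel()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ScalarField2D":
        df = pd.read_csv(path)
        nx, ny = df["i"].max() + 1, df["j"].max() + 1
        vals = np.full((nx, ny), np.nan)
        vals[df["i"].to_numpy(), df["j"].to_numpy()] = df["value"].to_numpy()
        return cls(values=vals, **kw)


@dataclass
class TensorField2D:
    components: np.ndarray             # (6, nx, ny) symmetric storage
    spacing: float = 1.0
    n_frames_averaged: int = 1

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape[0] != 6 or self.components.ndim != 3:
            raise ValueError("TensorField2D requires shape (6, nx, ny)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.components.shape[1:]

    def comp(self, name: str) -> np.ndarray:
        return self.components[SYM_COMPONENTS.index(name)]

    def full(self) -> np.ndarray:
        """Dense (nx, ny, 3, 3) symmetric tensor array."""
        xx, yy, zz, xy, xz, yz = self.components
        out = np.empty(self.shape + (3, 3))
        out[..., 0, 0], out[..., 1, 1], out[..., 2, 2] = xx, yy, zz
        out[..., 0, 1] = out[..., 1, 0] = xy
        out[..., 0, 2] = out[..., 2, 0] = xz
        out[..., 1, 2] = out[..., 2, 1] = yz
        return out

    def save(self, path: str | Path) -> None:
        np.savez_compressed(Path(path), components=self.components,
                            spacing=self.spacing,
                            n_frames_averaged=self.n_frames_averaged)

    @classmethod
    def load(cls, path: str | Path) -> "TensorField2D":
        with np.load(path, allow_pickle=False) as z:
            return cls(components=z["components"], spacing=float(z["spacing"]),
                       n_frames_averaged=int(z["n_frames_averaged"]))

    def to_csv(self, path: str | Path) -> None:
        nx, ny = self.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        data = {"i": ii.ravel(), "j": jj.ravel()}
        for k, name in enumerate(SYM_COMPONENTS):
            data[name] = self.components[k].ravel()
        pd.DataFrame(data).to_csv(path, index=False)
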