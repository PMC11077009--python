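"""Threshold percolation on 2D scalar fields.

A field is occupied at sites whose value is strictly greater than the
(1-p)x100th percentile of its own value distribution, so on an i.i.d.
continuous field the construction is exactly site percolation at occupation
probability p.  Connected clusters (4- or 8-neighbour), spanning-cluster
density P, second-moment average cluster size S, and the cluster-gyration
correlation length xi are measured per subsystem; ensembles of realizations
and subsystem sizes feed the finite-size-scaling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import ScalarField2D

__all__ = [
    "OccupancyGrid",
    "ClusterLabels",
    "PercolationCurves",
    "threshold_field",
    "label_clusters",
    "spanning_density",
    "average_cluster_size",
    "correlation_length",
    "percolation_curves",
]

_STRUCTURES = {
    "face4": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    "moore8": np.ones((3, 3), dtype=bool),
}


class DegenerateFieldError(ValueError):
    """Raised when percentile thresholding is ill-defined (massive ties)."""


@dataclass
class OccupancyGrid:
    occupied: np.ndarray           # bool (n, n) or (nx, ny)
    connectivity: str = "face4"    # face4 | moore8
    extent: int = 0                # characteristic length ell (side - 1)

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if not self.extent:
            self.extent = self.occupied.shape[0] - 1


@dataclass
class ClusterLabels:
    labels: np.ndarray             # int array, 0 = unoccupied
    sizes: np.ndarray              # (n_clusters,) site counts, label k -> sizes[k-1]
    spanning: np.ndarray           # (n_clusters,) bool
    rg2: np.ndarray                # (n_clusters,) squared radius of gyration
    connectivity: str = "face4"

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _values_of(field) -> np.ndarray:
    return field.values if isinstance(field, ScalarField2D) else np.asarray(field, dtype=float)


def threshold_field(field, p: float, connectivity: str = "face4") -> OccupancyGrid:
    """Occupy sites strictly above the (1-p)x100th percentile of the field.

    p = 0 occupies nothing; p = 1 occupies every site (the strict rule would
    otherwise exclude the minimum-valued site — documented convention).
    """
    vals = _values_of(field)
    if not 0.0 <= p <= 1.0:
        raise ValueError("occupation probability p must lie in [0, 1]")
    if p == 0.0:
        occ = np.zeros(vals.shape, dtype=bool)
    elif p == 1.0:
        occ = np.ones(vals.shape, dtype=bool)
    else:
        if vals.max() == vals.min():
            raise DegenerateFieldError(
                "constant field: the strict '>' percentile rule cannot realize "
                f"occupied fraction {p}; all values tie at the threshold"
            )
        thr = np.quantile(vals, 1.0 - p)
        occ = vals > thr
    return OccupancyGrid(occupied=occ, connectivity=connectivity)


def label_clusters(grid: OccupancyGrid) -> ClusterLabels:
    """Connected-component labeling with per-cluster size, gyration radius
    and spanning flag (touching both opposite edges in either axis; open
    boundaries)."""
    structure = _STRUCTURES[grid.connectivity]
    labels, n = ndimage.label(grid.occupied, structure=structure)
    if n == 0:
        z = np.zeros(0)
        return ClusterLabels(labels, z.astype(int), z.astype(bool), z,
                             grid.connectivity)
    lab = labels.ravel()
    nx, ny = labels.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj = ii.ravel().astype(float), jj.ravel().astype(float)
    sizes = np.bincount(lab, minlength=n + 1)[1:]
    sx = np.bincount(lab, weights=ii, minlength=n + 1)[1:]
    sy = np.bincount(lab, weights=jj, minlength=n + 1)[1:]
    sx2 = np.bincount(lab, weights=ii * ii, minlength=n + 1)[1:]
    sy2 = np.bincount(lab, weights=jj * jj, minlength=n + 1)[1:]
    with np.errstate(invalid="ignore"):
        rg2 = (sx2 / sizes - (sx / sizes) ** 2) + (sy2 / sizes - (sy / sizes) ** 2)
    rg2 = np.maximum(rg2, 0.0)

    spanning = np.zeros(n, dtype=bool)
    for axis_pair in (
        (np.unique(labels[0, :]), np.unique(labels[-1, :])),
        (np.unique(labels[:, 0]), np.unique(labels[:, -1])),
    ):
        both = np.intersect1d(axis_pair[0], axis_pair[1])
        both = both[both > 0]
        spanning[both - 1] = True
    return ClusterLabels(labels, sizes.astype(int), spanning, rg2,
                         grid.connectivity)


def spanning_density(labels: ClusterLabels) -> float:
    """Fraction of all lattice sites belonging to a spanning cluster."""
    total = labels.labels.size
    if labels.n_clusters == 0 or not labels.spanning.any():
        return 0.0
    return float(labels.sizes[labels.spanning].sum()) / total


def average_cluster_size(labels: ClusterLabels, method: str = "second_moment") -> float:
    """Average size of finite (non-spanning) clusters.

    Default is the second-moment ratio sum s^2 n_s / sum s n_s — the
    definition under which S diverges as |p - pc|^(-gamma); ``method="mean"``
    gives the arithmetic mean cluster size instead.  Returns 0 when no
    finite cluster exists.
    """
    s = labels.sizes[~labels.spanning] if labels.n_clusters else np.empty(0)
    if s.size == 0:
        return 0.0
    if method == "second_moment":
        return float((s.astype(float) ** 2).sum() / s.sum())
    if method == "mean":
        return float(s.mean())
    raise ValueError(f"unknown method {method!r}")


def correlation_length(labels: ClusterLabels) -> float:
    """Cluster-size-weighted pair distance: xi^2 = sum 2 Rg^2 s^2 / sum s^2
    over finite clusters (equals the mean squared distance between two sites
    of the same cluster, weighted by s^2).  NaN when no finite cluster."""
    m = ~labels.spanning if labels.n_clusters else np.zeros(0, dtype=bool)
    s = labels.sizes[m].astype(float)
    if s.size == 0:
        return float("nan")
    rg2 = labels.rg2[m]
    xi2 = float((2.0 * rg2 * s**2).sum() / (s**2).sum())
    return float(np.sqrt(max(xi2, 0.0)))


@dataclass
class PercolationCurves:
    """P, S, xi and spanning probability Pi over (p, ell, realization).

    Per-(ell) arrays are shaped (n_realizations, n_p); realization means are
    exposed by the ``mean_*`` accessors.  Per-realization storage is what the
    bootstrap stage resamples.
    """

    p: np.ndarray
    ells: list[int]
    P: dict[int, np.ndarray]
    S: dict[int, np.ndarray]
    xi: dict[int, np.ndarray]
    Pi: dict[int, np.ndarray]
    connectivity: str = "face4"
    metadata: dict = dc_field(default_factory=dict)

    def n_realizations(self, ell: int) -> int:
        return self.P[ell].shape[0]

    def mean(self, observable: str, ell: int) -> np.ndarray:
        arr = getattr(self, observable)[ell]
        return np.nanmean(arr, axis=0)

    def sem(self, observable: str, ell: int) -> np.ndarray:
        arr = getattr(self, observable)[ell]
        n = arr.shape[0]
        return np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ell in self.ells:
            rows.append(pd.DataFrame({
                "ell": ell,
                "p": self.p,
                "Pi": self.mean("Pi", ell),
                "P": self.mean("P", ell),
                "S": self.mean("S", ell),
                "xi": self.mean("xi", ell),
                "n_realizations": self.n_realizations(ell),
            }))
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _subsystem_views(vals: np.ndarray, side: int) -> list[np.ndarray]:
    """Non-overlapping side x side tiles of a field (open boundaries)."""
    nx, ny = vals.shape
    views = []
    for i0 in range(0, nx - side + 1, side):
        for j0 in range(0, ny - side + 1, side):
            views.append(vals[i0:i0 + side, j0:j0 + side])
    return views


def _measure_subsystem(vals: np.ndarray, thresholds: np.ndarray,
                       structure: np.ndarray, connectivity: str):
    """P, S, xi, Pi of one subsystem over a vector of thresholds."""
    n_p = len(thresholds)
    P = np.empty(n_p)
    S = np.empty(n_p)
    xi = np.empty(n_p)
    Pi = np.empty(n_p)
    for k, thr in enumerate(thresholds):
        occ = vals > thr  # thr = -inf / +inf handle p = 1 / p = 0 exactly
        grid = OccupancyGrid(occ, connectivity)
        labels = label_clusters(grid)
        P[k] = spanning_density(labels)
        S[k] = average_cluster_size(labels)
        xi[k] = correlation_length(labels)
        Pi[k] = 1.0 if (labels.n_clusters and labels.spanning.any()) else 0.0
    return P, S, xi, Pi


def percolation_curves(fields, p_grid, ells=None, connectivity: str = "face4",
                       metadata: dict | None = None) -> PercolationCurves:
    """Measure percolation observables over an ensemble of 2D fields.

    ``fields`` is an iterable of realizations (2D arrays or ScalarField2D).
    For each characteristic length ``ell`` the field is tiled into
    non-overlapping (ell+1)^2-site subsystems, each thresholded at every p of
    the grid against its own percentile; subsystem results are averaged
    within a realization.  ``ells=None`` uses the full field (ell = side-1).
    """
    p_grid = np.asarray(p_grid, dtype=float)
    structure = _STRUCTURES[connectivity]
    fields = [(_values_of(f)) for f in fields]
    if not fields:
        raise ValueError("no fields given")
    if ells is None:
        ells_by_field = True
        ells_list = sorted({f.shape[0] - 1 for f in fields})
    else:
        ells_by_field = False
        ells_list = sorted(int(e) for e in ells)
        for ell in ells_list:
            if any(ell + 1 > min(f.shape) for f in fields):
                raise ValueError(
                    f"subsystem side {ell + 1} exceeds a field extent; "
                    f"largest usable ell is {min(min(f.shape) for f in fields) - 1}"
                )

    acc = {ell: {"P": [], "S": [], "xi": [], "Pi": []} for ell in ells_list}
    for vals in fields:
        for ell in ells_list:
            side = ell + 1
            if ells_by_field and vals.shape[0] - 1 != ell:
                continue
            if side > min(vals.shape):
                continue
            subs = _subsystem_views(vals, side)
            res = np.zeros((4, len(p_grid)))
            for sub in subs:
                # vectorized per-subsystem thresholds for the whole p grid
                with np.errstate(invalid="ignore"):
                    thrs = np.quantile(sub, 1.0 - p_grid)
                thrs[p_grid >= 1.0] = -np.inf
                thrs[p_grid <= 0.0] = np.inf
                P, S, xi, Pi = _measure_subsystem(sub, thrs, structure, connectivity)
                res += np.array([P, S, np.nan_to_num(xi), Pi])
            res /= len(subs)
            acc[ell]["P"].append(res[0])
            acc[ell]["S"].append(res[1])
            acc[ell]["xi"].append(res[2])
            acc[ell]["Pi"].append(res[3])

    def pack(key):
        return {ell: np.array(acc[ell][key]) for ell in ells_list}

    return PercolationCurves(p=p_grid, ells=ells_list, P=pack("P"), S=pack("S"),
                             xi=pack("xi"), Pi=pack("Pi"),
                             connectivity=connectivity,
                             metadata=metadata or {})
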