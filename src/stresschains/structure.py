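"""Solid/liquid structural diagnostics.

The in-plane pair correlation function g(r) of (time-averaged) cell
positions distinguishes a solid-like monolayer — dominant peak near one cell
diameter, r/R0 ~ 2 — from a liquid-like one, where time-averaged positions
of different cells overlap and the dominant peak sits well below the cell
diameter.  A 2D static structure factor on the allowed wavevectors of the
periodic box provides an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairCorrelation",
    "pair_correlation",
    "structure_factor_2d",
    "classify_state",
    "StateReport",
]


@dataclass
class PairCorrelation:
    r_centers: np.ndarray   # bin centers, in units of R0
    g: np.ndarray
    n_pairs: np.ndarray     # ordered same-bin pair counts
    rho: float              # in-plane number density
    N: int
    R0: float
    bin_width: float        # in length units (not R0 units)


def _min_image(diff: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    for k in (0, 1):
        diff[..., k] -= box[k] * np.round(diff[..., k] / box[k])
    return diff


def pair_correlation(positions: np.ndarray, box: tuple[float, float],
                     R0: float, bin_width: float | None = None,
                     r_max: float | None = None) -> PairCorrelation:
    """Radial distribution function of in-plane points in a periodic box.

    Minimum-image distances are binned and normalized by N, the density rho
    and the annulus measure, so a uniform random configuration gives g ~ 1.
    Default bin width R0/20, default r_max = min(box)/2.
    """
    positions = np.asarray(positions, dtype=float)[:, :2]
    N = len(positions)
    if N < 2:
        raise ValueError("pair_correlation requires N >= 2 points")
    if bin_width is None:
        bin_width = R0 / 20.0
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if r_max is None:
        r_max = min(box) / 2.0

    diff = _min_image(positions[:, None, :] - positions[None, :, :], box)
    dist = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(N, k=1)
    d = dist[iu]

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    counts = counts * 2  # ordered pairs
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    rho = N / (box[0] * box[1])
    g = counts / (N * rho * area)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return PairCorrelation(r_centers=centers / R0, g=g, n_pairs=counts,
                           rho=rho, N=N, R0=R0, bin_width=bin_width)


def structure_factor_2d(positions: np.ndarray, box: tuple[float, float],
                        n_max: int = 16) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static structure factor S(q) = |sum_j exp(i q.r_j)|^2 / N on the
    allowed wavevectors q = 2 pi (nx/Lx, ny/Ly), n in [-n_max, n_max].

    Returns (qx, qy, S) with S shaped (2 n_max + 1, 2 n_max + 1); S at q=0
    equals N by construction.
    """
    positions = np.asarray(positions, dtype=float)[:, :2]
    N = len(positions)
    n = np.arange(-n_max, n_max + 1)
    qx = 2.0 * np.pi * n / box[0]
    qy = 2.0 * np.pi * n / box[1]
    ph_x = np.exp(1j * np.outer(qx, positions[:, 0]))   # (nq, N)
    ph_y = np.exp(1j * np.outer(qy, positions[:, 1]))
    amp = np.einsum("an,bn->ab", ph_x, ph_y)
    return qx, qy, (np.abs(amp) ** 2) / N


def time_averaged_pair_correlation(centroids: np.ndarray,
                                   box: tuple[float, float], R0: float,
                                   discard: float = 0.25, stride: int = 10,
                                   bin_width: float | None = None,
                                   r_max: float | None = None) -> PairCorrelation:
    """g(r) with the configurational average taken over trajectory frames.

    ``centroids`` is the (n_frames, N, >=2) trajectory; the first ``discard``
    fraction is dropped as transient and every ``stride``-th frame binned.
    This is the time-averaged pair correlation of the evolving monolayer: in
    a caged solid it peaks at one cell diameter, while transient overlaps in
    a liquid put weight well below the diameter.
    """
    n_frames = centroids.shape[0]
    t0 = int(discard * n_frames)
    frames = range(t0, n_frames, stride)
    if not frames:
        raise ValueError("no frames left after discard/stride selection")
    acc = None
    count = 0
    for t in frames:
        gr = pair_correlation(centroids[t], box, R0, bin_width=bin_width,
                              r_max=r_max)
        if acc is None:
            acc = gr
            acc_g = gr.g.astype(float)
            acc_n = gr.n_pairs.astype(float)
        else:
            acc_g += gr.g
            acc_n += gr.n_pairs
        count += 1
    return PairCorrelation(r_centers=acc.r_centers, g=acc_g / count,
                           n_pairs=acc_n / count, rho=acc.rho, N=acc.N,
                           R0=R0, bin_width=acc.bin_width)


@dataclass
class StateReport:
    label: str                      # solid | liquid | indeterminate
    peaks: list = field(default_factory=list)   # (r_over_R0, height), sorted by height desc
    dominant: tuple | None = None


def classify_state(gr: PairCorrelation,
                   min_r: float = 0.2,
                   solid_window: tuple[float, float] = (1.6, 2.4),
                   liquid_max: float = 1.2,
                   height_factor: float = 1.05,
                   smooth_bins: int = 3) -> StateReport:
    """Label a g(r) as solid-like or liquid-like from its dominant peak.

    The self-overlap region r/R0 < ``min_r`` is excluded; peaks are local
    maxima of the ``smooth_bins``-bin moving average exceeding
    ``height_factor`` times the large-r baseline.  Solid: dominant peak
    within ``solid_window`` (one cell diameter); liquid: dominant peak below
    ``liquid_max``; anything else (or no peak) is indeterminate.
    """
    g = np.asarray(gr.g, dtype=float)
    r = np.asarray(gr.r_centers, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        g = np.convolve(g, kernel, mode="same")
    baseline = max(float(np.median(g[g > 0])) if np.any(g > 0) else 1.0, 1e-12)

    peaks = []
    for k in range(1, len(g) - 1):
        if r[k] < min_r:
            continue
        if g[k] >= g[k - 1] and g[k] > g[k + 1] and g[k] > height_factor * baseline:
            peaks.append((float(r[k]), float(g[k])))
    peaks.sort(key=lambda t: -t[1])
    if not peaks:
        return StateReport(label="indeterminate", peaks=[])
    dominant = peaks[0]
    if solid_window[0] <= dominant[0] <= solid_window[1]:
        label = "solid"
    elif dominant[0] < liquid_max:
        label = "liquid"
    else:
        label = "indeterminate"
    return StateReport(label=label, peaks=peaks, dominant=dominant)
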