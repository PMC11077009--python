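"""Time evolution of the monolayer.

One explicit step advances every cell field by relaxational (Model A)
dynamics plus advection by the cell's own rigid-body velocity,

    d phi_i / dt + v_i . grad phi_i = -Gamma dF/dphi_i,

with the overdamped force balance  xi v_i = T_i + alpha p_i  where
T_i = int (dF/dphi_i) grad phi_i dx  is the passive traction (the force the
free-energy landscape exerts on cell i) and p_i the in-plane polarity unit
vector.  Polarity relaxes toward the traction direction (contact inhibition
of locomotion) with rotational noise.

Sign convention: the traction is stored with the sign that makes overdamped
motion descend the free-energy landscape (repulsion pushes overlapping cells
apart, adhesion pulls them together); this is the convention under which the
energy-descent property of the passive dynamics holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._grid import gradient, upwind_advection, _shift_z
from .energy import free_energy, functional_derivative_stack
from .monolayer import CellState, MonolayerState, init_monolayer
from .params import ModelParams

__all__ = [
    "cell_traction",
    "interaction_traction",
    "update_polarity",
    "advance",
    "run_simulation",
    "Trajectory",
    "SimulationDiverged",
]


class SimulationDiverged(RuntimeError):
    """Raised when a field becomes non-finite mid-run; names the step."""

    def __init__(self, step: int, trajectory: "Trajectory | None" = None):
        super().__init__(f"non-finite field at step {step}; run aborted")
        self.step = step
        self.trajectory = trajectory


def _wrap_angle(theta: float) -> float:
    return (theta + math.pi) % (2.0 * math.pi) - math.pi


def _tractions_from_stack(phi: np.ndarray, dF: np.ndarray, a0: float) -> np.ndarray:
    """Per-cell traction T_i = int (dF/dphi_i) grad phi_i dx, shape (N, 3)."""
    gx, gy, gz = gradient(phi, a0)
    dV = a0**3
    return np.stack(
        [
            np.sum(dF * gx, axis=(1, 2, 3)),
            np.sum(dF * gy, axis=(1, 2, 3)),
            np.sum(dF * gz, axis=(1, 2, 3)),
        ],
        axis=1,
    ) * dV


#: cache of (wall ref, wall^2, laplacian(wall)) keyed by id — the substrate
#: field is static by contract, so its derivatives never change within a run
_WALL_CACHE: dict[int, tuple] = {}


def _wall_derivatives(wall: np.ndarray, a0: float):
    from ._grid import laplacian
    key = id(wall)
    hit = _WALL_CACHE.get(key)
    if hit is None or hit[0] is not wall:
        _WALL_CACHE.clear()
        _WALL_CACHE[key] = hit = (wall, wall * wall, laplacian(wall, a0))
    return hit[1], hit[2]


def _step_forces(phi: np.ndarray, wall: np.ndarray, params: ModelParams):
    """Assemble dF/dphi, total tractions and interaction tractions with
    shared intermediates (one Laplacian, one gradient pass)."""
    from ._grid import laplacian
    a0 = params.a0
    dV = a0**3
    V0 = params.V0

    phi2 = phi * phi
    sum_phi2 = phi2.sum(axis=0)
    lap = laplacian(phi, a0)
    volumes = phi2.sum(axis=(1, 2, 3)) * dV

    # interaction part (kappa_cc, omega_cc) — also drives CIL polarity
    dF_int = (4.0 * params.coef_rep_cc) * phi * (sum_phi2 - phi2)
    if params.coef_adh_cc != 0.0:
        dF_int -= (2.0 * params.coef_adh_cc) * (lap.sum(axis=0) - lap)

    dF = params.coef_bulk * (
        8.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi) - (2.0 * params.lam**2) * lap
    )
    dF += dF_int
    dF -= (4.0 * params.mu / V0) * (1.0 - volumes / V0)[:, None, None, None] * phi
    wall2, wall_lap = _wall_derivatives(wall, a0)
    dF += (2.0 * params.coef_rep_cw) * phi * wall2
    if params.coef_adh_cw != 0.0:
        dF -= params.coef_adh_cw * wall_lap

    gx, gy, gz = gradient(phi, a0)
    tr = np.stack([np.sum(dF * gx, axis=(1, 2, 3)),
                   np.sum(dF * gy, axis=(1, 2, 3)),
                   np.sum(dF * gz, axis=(1, 2, 3))], axis=1) * dV
    tr_int = np.stack([np.sum(dF_int * gx, axis=(1, 2, 3)),
                       np.sum(dF_int * gy, axis=(1, 2, 3)),
                       np.sum(dF_int * gz, axis=(1, 2, 3))], axis=1) * dV
    return dF, tr, tr_int


def interaction_traction(state: MonolayerState, params: ModelParams,
                         i: int) -> np.ndarray:
    """Cell-cell interaction traction of cell ``i`` (drives CIL polarity)."""
    if not 0 <= i < state.N:
        raise IndexError(f"cell index {i} out of range for N={state.N}")
    phi = state.phi_stack()
    return _step_forces(phi, state.wall, params)[2][i]


def cell_traction(state: MonolayerState, params: ModelParams, i: int) -> np.ndarray:
    """Passive traction 3-vector of cell ``i``."""
    if not 0 <= i < state.N:
        raise IndexError(f"cell index {i} out of range for N={state.N}")
    phi = state.phi_stack()
    dF = functional_derivative_stack(state, params)
    return _tractions_from_stack(phi, dF, params.a0)[i]


def update_polarity(theta: float, traction: np.ndarray, params: ModelParams,
                    rng: np.random.Generator, dt: float | None = None) -> float:
    """One Euler–Maruyama step of the polarity angle.

    Drift rotates the polarity toward the in-plane traction direction with
    rate |T|/tau_pol (zero traction => zero drift, by convention); noise is
    Dr * sqrt(dt) * eta with eta ~ N(0,1), i.e. Dr enters literally as the
    noise amplitude.  The drift factor is capped at 1 so a single explicit
    step never over-rotates past alignment.
    """
    if dt is None:
        dt = params.dt
    # in-plane projection: the polarity is planar, and contact-inhibition
    # realignment responds to in-plane interaction forces (the substrate-
    # normal force component carries no in-plane directional information)
    tmag = math.hypot(float(traction[0]), float(traction[1]))
    drift = 0.0
    if tmag > 0.0:
        tdir = math.atan2(float(traction[1]), float(traction[0]))
        dtheta = _wrap_angle(theta - tdir)  # signed angle traction -> polarity
        c = min(dt * tmag / params.tau_pol, 1.0)
        drift = -c * dtheta
    noise = params.Dr * math.sqrt(dt) * float(rng.standard_normal())
    return _wrap_angle(theta + drift + noise)


def _circular_centroid(w: np.ndarray, a0: float) -> np.ndarray:
    """Mass centroid of a weight field, periodic in x/y (circular mean)."""
    nx, ny, nz = w.shape
    tot = w.sum()
    out = np.empty(3)
    for axis, n in ((0, nx), (1, ny)):
        ang = 2.0 * math.pi * np.arange(n) / n
        prof = w.sum(axis=tuple(a for a in range(3) if a != axis))
        c = float(prof @ np.cos(ang))
        s = float(prof @ np.sin(ang))
        out[axis] = (math.atan2(s, c) % (2.0 * math.pi)) / (2.0 * math.pi) * n * a0
    zprof = w.sum(axis=(0, 1))
    out[2] = float(zprof @ np.arange(nz)) / tot * a0
    return out


def advance(state: MonolayerState, params: ModelParams,
            rng: np.random.Generator) -> MonolayerState:
    """One explicit Euler step; returns a new state, inputs untouched."""
    a0 = params.a0
    nx, ny, nz = params.grid
    Lx, Ly = nx * a0, ny * a0

    phi = state.phi_stack()
    if not np.isfinite(phi).all():
        bad = [i for i in range(state.N)
               if not np.isfinite(state.cells[i].phi).all()]
        raise FloatingPointError(f"non-finite phase field in cell(s) {bad}")
    # polarity realigns to the cell-cell interaction force only (self-drag
    # and substrate forces carry no contact information)
    dF, tractions, int_tractions = _step_forces(phi, state.wall, params)

    pol = np.array([[math.cos(c.theta), math.sin(c.theta), 0.0] for c in state.cells])
    velocities = (tractions + params.alpha * pol) / params.xi_fric

    vmax = float(np.abs(velocities).max())
    if vmax * params.dt / a0 > params.cfl_max:
        raise RuntimeError(
            f"CFL violation at step {state.time}: max|v|*dt/a0 = "
            f"{vmax * params.dt / a0:.3f} > {params.cfl_max}; reduce dt"
        )

    # stack-vectorized upwind advection: per-cell constant velocity, split
    # into positive/negative parts selecting the one-sided difference
    vb = velocities.astype(phi.dtype)[:, :, None, None, None]
    adv = np.maximum(vb[:, 0], 0) * (phi - np.roll(phi, 1, -3)) \
        + np.minimum(vb[:, 0], 0) * (np.roll(phi, -1, -3) - phi) \
        + np.maximum(vb[:, 1], 0) * (phi - np.roll(phi, 1, -2)) \
        + np.minimum(vb[:, 1], 0) * (np.roll(phi, -1, -2) - phi)
    adv += np.maximum(vb[:, 2], 0) * (phi - _shift_z(phi, -1)) \
        + np.minimum(vb[:, 2], 0) * (_shift_z(phi, 1) - phi)
    adv /= a0

    newphi = phi + params.dt * (-params.Gamma * dF - adv)
    # count only material overshoots; far-field values dither around 0
    # at machine precision and are clipped silently
    tol = 1e-9
    clamped = int((newphi < -tol).sum() + (newphi > 1.0 + tol).sum())
    np.clip(newphi, 0.0, 1.0, out=newphi)

    new = MonolayerState(cells=[], wall=state.wall, time=state.time + 1,
                         clamp_events=state.clamp_events + clamped,
                         low_volume_flags=list(state.low_volume_flags))
    for i in range(state.N):
        f = newphi[i]
        cell = CellState(phi=f, theta=state.cells[i].theta,
                         centroid=state.cells[i].centroid.copy())
        new.cells.append(cell)
        cell.traction = tractions[i].copy()
        cell.velocity = velocities[i].copy()
        # centroid: wrapped position from the field, unwrapped by min-image
        wrapped = _circular_centroid(f * f, a0)
        old_wrapped = np.array([
            state.cells[i].centroid[0] % Lx,
            state.cells[i].centroid[1] % Ly,
            state.cells[i].centroid[2],
        ])
        disp = wrapped - old_wrapped
        disp[0] -= Lx * round(disp[0] / Lx)
        disp[1] -= Ly * round(disp[1] / Ly)
        cell.centroid = state.cells[i].centroid + disp
        cell.theta = update_polarity(cell.theta, int_tractions[i], params, rng)
        if cell.volume(a0) < 0.5 * params.V0 and i not in new.low_volume_flags:
            new.low_volume_flags.append(i)
    return new


@dataclass
class Trajectory:
    """Recorded output of a run: per-step cell diagnostics plus snapshots."""

    params: ModelParams
    centroids: np.ndarray        # (n_steps+1, N, 3), unwrapped
    thetas: np.ndarray           # (n_steps+1, N)
    tractions: np.ndarray        # (n_steps+1, N, 3)
    volumes: np.ndarray          # (n_steps+1, N)
    energies: list[tuple[int, float]] = dc_field(default_factory=list)
    snapshots: list[tuple[int, MonolayerState]] = dc_field(default_factory=list)
    stress_mean: "object | None" = None   # TensorField2D when recorded
    clamp_events: int = 0

    @property
    def n_steps(self) -> int:
        return self.centroids.shape[0] - 1

    @property
    def box(self) -> tuple[float, float]:
        nx, ny, _ = self.params.grid
        return (nx * self.params.a0, ny * self.params.a0)

    def time_averaged_positions(self, discard: float = 0.25) -> np.ndarray:
        """In-plane (N, 2) positions averaged over the last (1-discard) of the
        run, on unwrapped trajectories, then wrapped back into the box."""
        t0 = int(discard * self.centroids.shape[0])
        mean = self.centroids[t0:, :, :2].mean(axis=0)
        Lx, Ly = self.box
        mean[:, 0] %= Lx
        mean[:, 1] %= Ly
        return mean

    def max_displacement(self) -> float:
        """Largest in-plane excursion of any cell from its initial position."""
        d = self.centroids[:, :, :2] - self.centroids[0, :, :2]
        return float(np.sqrt((d**2).sum(axis=2)).max())


def run_simulation(params: ModelParams,
                   snapshot_every: int = 0,
                   stress_every: int = 0,
                   energy_every: int = 0,
                   progress: bool = False) -> Trajectory:
    """Run ``params.n_sim`` recorded steps from the seeded initial state.

    Fully reproducible from (params, seed).  When ``stress_every`` > 0, the
    coarse-grained stress tensor field is accumulated at that stride and the
    time average stored on the trajectory.
    """
    from .stress import coarse_grained_stress, nodal_traction_field, time_average

    params.check()
    rng = np.random.default_rng(params.seed)
    state = init_monolayer(params, rng)
    N, T = params.N, params.n_sim

    centroids = np.empty((T + 1, N, 3))
    thetas = np.empty((T + 1, N))
    tractions = np.zeros((T + 1, N, 3))
    volumes = np.empty((T + 1, N))
    energies: list[tuple[int, float]] = []
    snapshots: list[tuple[int, MonolayerState]] = []
    stress_frames = []

    def record(t: int, st: MonolayerState) -> None:
        for i, c in enumerate(st.cells):
            centroids[t, i] = c.centroid
            thetas[t, i] = c.theta
            tractions[t, i] = c.traction
            volumes[t, i] = c.volume(params.a0)
        if energy_every and t % energy_every == 0:
            energies.append((t, free_energy(st, params)))
        if snapshot_every and t % snapshot_every == 0:
            snapshots.append((t, st.copy()))

    record(0, state)
    iterator = range(1, T + 1)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="simulate")
        except ImportError:
            pass
    for t in iterator:
        state = advance(state, params, rng)
        if not np.isfinite(state.cells[0].phi).all():
            raise SimulationDiverged(t)
        record(t, state)
        if stress_every and t % stress_every == 0:
            tf = nodal_traction_field(state, params)
            stress_frames.append(coarse_grained_stress(tf))

    traj = Trajectory(
        params=params,
        centroids=centroids,
        thetas=thetas,
        tractions=tractions,
        volumes=volumes,
        energies=energies,
        snapshots=snapshots,
        stress_mean=time_average(stress_frames) if stress_frames else None,
        clamp_events=state.clamp_events,
    )
    return traj
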