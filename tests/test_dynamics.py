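"""Traction, polarity and time stepping: oracles and conservation checks."""

import dataclasses
import math

import numpy as np
import pytest

from stresschains import ModelParams
from stresschains.dynamics import (advance, cell_traction, run_simulation,
                                   update_polarity)
from stresschains.energy import free_energy, functional_derivative
from stresschains._grid import gradient
from stresschains.monolayer import init_monolayer


def _relax(params, n, rng=None):
    if rng is None:
        rng = np.random.default_rng(params.seed)
    st = init_monolayer(params, rng)
    for _ in range(n):
        st = advance(st, params, rng)
    return st, rng


# ----------------------------------------------------------------- traction

def test_traction_vanishes_for_symmetric_isolated_cell():
    """A spherically symmetric cell with no wall-gradient asymmetry exerts
    no net traction (discrete reflection symmetry)."""
    from stresschains.monolayer import CellState, MonolayerState, tanh_sphere
    p = ModelParams(N=1, R0=5.0, grid=(24, 24, 16), seed=0,
                    omega_cw=0.0, kappa_cw=0.0)
    c = np.array([12.0, 12.0, 7.5])  # symmetric about nodes / z mid-plane
    st = MonolayerState(cells=[CellState(tanh_sphere(c, p.R0, p), 0.0, c)],
                        wall=np.zeros(p.grid))
    T = cell_traction(st, p, 0)
    assert np.linalg.norm(T) < 1e-8 * (p.E * p.R0**2)


def test_pairwise_interaction_antisymmetry(two_cell_state):
    """Passive cell-cell forces cancel to 1e-6 relative (in-plane; the wall
    breaks z-symmetry but not x/y)."""
    p, st = two_cell_state
    T0 = cell_traction(st, p, 0)
    T1 = cell_traction(st, p, 1)
    scale = max(np.linalg.norm(T0[:2]), 1e-30)
    assert np.linalg.norm((T0 + T1)[:2]) < 1e-6 * scale


def test_traction_matches_dense_node_sum(two_cell_state):
    """Vectorized traction equals an explicit per-node accumulation of
    (dF/dphi_i) grad phi_i."""
    p, st = two_cell_state
    i = 0
    dF = functional_derivative(st, p, i)
    gx, gy, gz = gradient(st.cells[i].phi, p.a0)
    acc = np.zeros(3)
    nx, ny, nz = p.grid
    for a, g in enumerate((gx, gy, gz)):
        s = 0.0
        for ix in range(nx):
            s += float(np.sum(dF[ix] * g[ix]))
        acc[a] = s * p.a0**3
    T = cell_traction(st, p, i)
    assert np.allclose(T, acc, rtol=1e-10, atol=1e-12)


# ----------------------------------------------------------------- polarity

def test_polarity_fixed_point_and_drift_sign():
    p = ModelParams(Dr=0.0)
    rng = np.random.default_rng(0)
    T = np.array([1.0, 0.0, 0.0])
    # aligned: unchanged
    assert update_polarity(0.0, T, p, rng) == pytest.approx(0.0, abs=1e-15)
    # theta = pi/2 with traction along +x: theta decreases toward 0
    th = update_polarity(math.pi / 2, T, p, rng)
    assert 0.0 < th < math.pi / 2
    # zero traction: no drift
    assert update_polarity(1.2, np.zeros(3), p, rng) == pytest.approx(1.2)


def test_polarity_noise_variance_matches_discretization():
    """With zero drift the variance of theta increments is Dr^2 dt within 5%."""
    p = ModelParams(Dr=0.4, dt=0.05)
    rng = np.random.default_rng(3)
    th, incs = 0.0, []
    for _ in range(10_000):
        new = update_polarity(th, np.zeros(3), p, rng)
        d = (new - th + math.pi) % (2 * math.pi) - math.pi
        incs.append(d)
        th = new
    var = np.var(incs)
    assert var == pytest.approx(p.Dr**2 * p.dt, rel=0.05)


# ----------------------------------------------------------------- stepping

def test_relaxed_cell_is_stationary():
    p = ModelParams(N=1, R0=5.0, grid=(24, 24, 24), seed=0, alpha=0.0, Dr=0.0)
    st, rng = _relax(p, 6000)
    before = st.cells[0].centroid.copy()
    st = advance(st, p, rng)
    assert np.linalg.norm(st.cells[0].centroid - before) < 1e-6 * p.a0


def test_energy_descends_without_activity(two_cell_state):
    """alpha = 0, Dr = 0: free energy is non-increasing per step (1e-6)."""
    p, st = two_cell_state
    p = dataclasses.replace(p, alpha=0.0, Dr=0.0)
    rng = np.random.default_rng(0)
    E = free_energy(st, p)
    for _ in range(100):
        st = advance(st, p, rng)
        E1 = free_energy(st, p)
        assert E1 <= E + 1e-6 * abs(E)
        E = E1


def test_single_cell_steady_speed_is_alpha_over_xi():
    """Overdamped force balance: an isolated self-propelled cell with frozen
    polarity cruises at alpha/xi within 5%."""
    p = ModelParams(N=1, R0=6.0, grid=(32, 32, 24), seed=2, alpha=0.3,
                    Dr=0.0, tau_pol=1e9)
    st = init_monolayer(p, np.random.default_rng(2))
    st.cells[0].theta = 0.3
    rng = np.random.default_rng(0)
    for _ in range(250):
        st = advance(st, p, rng)
    start = st.cells[0].centroid.copy()
    n = 100
    for _ in range(n):
        st = advance(st, p, rng)
    speed = np.linalg.norm((st.cells[0].centroid - start)[:2]) / (n * p.dt)
    assert speed == pytest.approx(p.alpha / p.xi_fric, rel=0.05)


def test_volume_drift_below_one_percent_per_1000_steps():
    p = ModelParams(N=1, R0=5.0, grid=(24, 24, 24), seed=0, alpha=0.0, Dr=0.0)
    st, rng = _relax(p, 300)   # relax first
    v0 = st.cells[0].volume()
    for _ in range(300):
        st = advance(st, p, rng)
    drift_per_1000 = abs(st.cells[0].volume() - v0) / v0 / 300 * 1000
    assert drift_per_1000 < 0.01


def test_relaxed_volume_within_five_percent_of_target():
    p = ModelParams(N=1, R0=5.0, grid=(24, 24, 24), seed=0, alpha=0.0, Dr=0.0)
    st, _ = _relax(p, 400)
    assert st.cells[0].volume() == pytest.approx(p.V0, rel=0.05)


def test_empty_run_returns_initial_state_only():
    p = ModelParams(N=4, R0=5.0, grid=(24, 24, 20), n_sim=0, seed=5)
    traj = run_simulation(p)
    assert traj.n_steps == 0
    assert traj.centroids.shape[0] == 1


def test_trajectories_are_bitwise_reproducible():
    p = ModelParams(N=4, R0=5.0, grid=(24, 24, 20), n_sim=25, seed=9,
                    alpha=0.5, Dr=0.3)
    t1 = run_simulation(p)
    t2 = run_simulation(p)
    assert np.array_equal(t1.centroids, t2.centroids)
    assert np.array_equal(t1.thetas, t2.thetas)
    assert np.array_equal(t1.tractions, t2.tractions)


def test_initial_states_are_bitwise_reproducible():
    p = ModelParams(N=9, R0=5.0, grid=(36, 32, 20), seed=4)
    s1 = init_monolayer(p)
    s2 = init_monolayer(p)
    for c1, c2 in zip(s1.cells, s2.cells):
        assert np.array_equal(c1.phi, c2.phi)
        assert c1.theta == c2.theta
    assert np.array_equal(s1.wall, s2.wall)


def test_init_examples():
    """Construction contracts: volume near target, distinct well-separated
    centroids, sizing error on an impossible box."""
    p = ModelParams(N=1, R0=8.0, grid=(32, 32, 32), seed=0)
    st = init_monolayer(p)
    assert st.cells[0].volume() == pytest.approx(p.V0, rel=0.10)

    p16 = ModelParams(N=16, R0=8.0, grid=(128, 128, 24), seed=1)
    st16 = init_monolayer(p16)
    pos = st16.centroids(box=(128.0, 128.0))
    assert len(pos) == 16
    for i in range(16):
        for j in range(i + 1, 16):
            d = pos[i, :2] - pos[j, :2]
            d -= 128.0 * np.round(d / 128.0)
            assert np.linalg.norm(d) > p16.R0 / 2

    with pytest.raises(ValueError, match="too small"):
        init_monolayer(ModelParams(N=16, R0=8.0, grid=(24, 24, 24), seed=0))


def test_wall_field_is_static_across_steps():
    p = ModelParams(N=2, R0=5.0, grid=(24, 20, 20), seed=1, alpha=0.5)
    st = init_monolayer(p)
    wall0 = st.wall.copy()
    rng = np.random.default_rng(0)
    for _ in range(5):
        st = advance(st, p, rng)
    assert np.array_equal(st.wall, wall0)
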