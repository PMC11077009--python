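"""Shared fixtures.

The desk-scale simulation fixtures are session-scoped because several tests
(structural classification, stress statistics, trajectory properties) read
the same runs; each takes a minute or two, so they are computed once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from stresschains import ModelParams
from stresschains.dynamics import run_simulation
from stresschains.monolayer import init_monolayer, tanh_sphere
from stresschains.synthetic import monolayer_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cell_state():
    """Two overlapping cells on a small grid — the workhorse interaction
    fixture for energy/traction oracles."""
    p = ModelParams(N=2, R0=5.0, grid=(24, 20, 20), lam=2.0, z_wall=3.0,
                    seed=1, kappa_cc=0.25, omega_cc=0.01)
    st = init_monolayer(p, np.random.default_rng(1))
    c0 = np.array([9.0, 10.0, 9.0])
    c1 = np.array([16.0, 10.0, 9.0])
    st.cells[0].phi = tanh_sphere(c0, p.R0, p)
    st.cells[1].phi = tanh_sphere(c1, p.R0, p)
    st.cells[0].centroid = c0
    st.cells[1].centroid = c1
    return p, st


@pytest.fixture(scope="session")
def solid_run():
    """Desk-scale N=16 run deep in the solid (caged) regime."""
    params, _ = monolayer_fixture(N=16, regime="solid_like", seed=7,
                                  n_sim=2000)
    return params, run_simulation(params)


@pytest.fixture(scope="session")
def liquid_run():
    """Desk-scale N=16 run on the liquid side (high adhesion + traction)."""
    params, _ = monolayer_fixture(N=16, regime="liquid_like", seed=7,
                                  n_sim=10000)
    return params, run_simulation(params)


def _sweep_run(omega_tilde: float, alpha_tilde: float, seed: int = 11,
               n_sim: int = 700, N: int = 9):
    base, _ = monolayer_fixture(N=N, regime="solid_like", seed=seed,
                                n_sim=n_sim)
    params = base.with_drives(omega_tilde=omega_tilde, alpha_tilde=alpha_tilde)
    return params, run_simulation(params, stress_every=20)


@pytest.fixture(scope="session")
def adhesion_sweep():
    """Two-control adhesion sweep (omega_tilde 0.2 vs 0.4) at fixed alpha."""
    return {w: _sweep_run(w, 0.2) for w in (0.2, 0.4)}


@pytest.fixture(scope="session")
def traction_sweep():
    """Two-control active-traction sweep (alpha_tilde 0.2 vs 0.6)."""
    return {a: _sweep_run(0.25, a) for a in (0.2, 0.6)}
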