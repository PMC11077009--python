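"""Stress coarse-graining: traction partition, dyadic stencil, scalar fields."""

import dataclasses
import math

import numpy as np
import pytest

from stresschains import ModelParams
from stresschains.fields import ScalarField2D, TensorField2D
from stresschains.monolayer import CellState, MonolayerState, init_monolayer
from stresschains.stress import (TractionField, coarse_grained_stress,
                                 field_statistics_sweep, isotropic_stress,
                                 max_inplane_shear, nodal_traction_field,
                                 out_of_plane_stress, susceptibility,
                                 time_average)


def _tensor(vals):
    """TensorField2D with the same 3x3 tensor at every node of a 4x4 grid."""
    xx, yy, zz, xy, xz, yz = vals
    comps = np.stack([np.full((4, 4), v, dtype=float)
                      for v in (xx, yy, zz, xy, xz, yz)])
    return TensorField2D(components=comps)


# ------------------------------------------------------------ traction field

def test_empty_monolayer_gives_zero_traction_field():
    p = ModelParams(N=1, R0=5.0, grid=(16, 16, 20), seed=0)
    st = MonolayerState(cells=[], wall=np.zeros(p.grid))
    tf = nodal_traction_field(st, p)
    assert np.all(tf.values == 0.0)


def test_traction_field_sums_to_cell_totals():
    """Partition property: summing the nodal field over all nodes recovers
    sum_i (T_i + alpha p_i) to 1e-6 relative."""
    p = ModelParams(N=2, R0=5.0, grid=(28, 24, 20), seed=3, alpha=0.7)
    st = init_monolayer(p, np.random.default_rng(3))
    from stresschains.dynamics import cell_traction
    expected = np.zeros(3)
    for i, c in enumerate(st.cells):
        expected += cell_traction(st, p, i) + p.alpha * c.polarity
    got = nodal_traction_field(st, p).total()
    assert np.allclose(got, expected, rtol=1e-6, atol=1e-9)


def test_traction_field_grid_mismatch_raises():
    p = ModelParams(N=1, R0=5.0, grid=(16, 16, 20), seed=0)
    st = MonolayerState(cells=[], wall=np.zeros((8, 8, 8)))
    with pytest.raises(ValueError, match="grid"):
        nodal_traction_field(st, p)


# ------------------------------------------------------- coarse-grained Eq.

def test_zero_traction_zero_stress():
    tf = TractionField(np.zeros((3, 8, 8, 6)))
    assert np.all(coarse_grained_stress(tf).components == 0.0)


@pytest.mark.parametrize("stencil", ["dual8", "face4"])
def test_uniform_traction_maps_to_zero_stress(stencil):
    """Sum of r_ij over a symmetric stencil vanishes, so a globally uniform
    traction produces exactly zero stress."""
    vals = np.zeros((3, 8, 8, 6))
    vals[0] = 1.3
    vals[1] = -0.4
    vals[2] = 0.9
    sig = coarse_grained_stress(TractionField(vals), stencil=stencil)
    assert np.allclose(sig.components, 0.0, atol=1e-12)


def test_stress_linearity():
    rng = np.random.default_rng(0)
    t1 = rng.standard_normal((3, 6, 6, 5))
    t2 = rng.standard_normal((3, 6, 6, 5))
    s1 = coarse_grained_stress(TractionField(t1)).components
    s2 = coarse_grained_stress(TractionField(t2)).components
    s12 = coarse_grained_stress(TractionField(t1 + t2)).components
    assert np.allclose(s12, s1 + s2, atol=1e-12)


def test_force_dipole_sign_and_bruteforce_oracle():
    """A repulsive contact pair (forces pushing the two nodes apart, the
    dominant cell-cell interaction) produces compressive (negative)
    sigma_xx at the dual node between the forces, while an attractive pair
    is tensile; cross-checked against an explicit hand-coded evaluation of
    the dyadic sum."""
    nx, ny, nz = 12, 8, 4
    vals = np.zeros((3, nx, ny, nz))
    zmid = 2
    vals[0, 5, 4, zmid] = -1.0   # at x=5, pushed toward -x (away from x=6)
    vals[0, 6, 4, zmid] = +1.0   # at x=6, pushed toward +x
    sig = coarse_grained_stress(TractionField(vals), stencil="dual8")
    sxx = sig.comp("xx")
    assert sxx[5, 3] < 0.0 and sxx[5, 4] < 0.0   # compressive at the contact
    attr = coarse_grained_stress(TractionField(-vals), stencil="dual8")
    assert attr.comp("xx")[5, 3] > 0.0           # attraction -> tension

    # brute-force oracle: loop over dual nodes and the 8 corner offsets
    oracle = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            acc = np.zeros((3, 3))
            for k in range(nz - 1):
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            r = np.array([0.5 - dx, 0.5 - dy, 0.5 - dz])
                            T = vals[:, (i + dx) % nx, (j + dy) % ny, k + dz]
                            acc += np.outer(r, T)
            oracle[i, j] = 0.5 * (acc + acc.T)[0, 0]
    assert np.allclose(sxx, oracle, atol=1e-12)


# ---------------------------------------------------------------- averaging

def test_time_average_identity_and_cancellation():
    rng = np.random.default_rng(1)
    f = TensorField2D(rng.standard_normal((6, 5, 5)))
    assert np.array_equal(time_average([f]).components, f.components)
    neg = TensorField2D(-f.components)
    assert np.allclose(time_average([f, neg]).components, 0.0, atol=1e-15)


def test_time_average_matches_loop_accumulation():
    rng = np.random.default_rng(2)
    frames = [TensorField2D(rng.standard_normal((6, 4, 4))) for _ in range(100)]
    acc = np.zeros((6, 4, 4))
    for f in frames:
        acc += f.components
    avg = time_average(frames)
    assert np.allclose(avg.components, acc / 100, atol=1e-12)
    assert avg.n_frames_averaged == 100


def test_time_average_contract_errors():
    with pytest.raises(ValueError):
        time_average([])
    a = TensorField2D(np.zeros((6, 4, 4)))
    b = TensorField2D(np.zeros((6, 5, 5)))
    with pytest.raises(ValueError):
        time_average([a, b])


# ------------------------------------------------------------- scalar fields

def test_isotropic_stress_values():
    assert np.allclose(isotropic_stress(_tensor([1, 1, 1, 0, 0, 0])).values, 1.0)
    # traceless (deviatoric) tensor
    dev = isotropic_stress(_tensor([1, -0.5, -0.5, 0.3, 0.2, 0.1]))
    assert np.allclose(dev.values, 0.0, atol=1e-12)


def test_isotropic_stress_matches_trace_loop():
    rng = np.random.default_rng(3)
    t = TensorField2D(rng.standard_normal((6, 7, 7)))
    iso = isotropic_stress(t).values
    full = t.full()
    for i in range(7):
        for j in range(7):
            assert iso[i, j] == pytest.approx(np.trace(full[i, j]) / 3.0, rel=1e-12)


def test_normalization_conventions():
    t = TensorField2D(np.zeros((6, 3, 3)))
    with pytest.raises(ValueError):
        isotropic_stress(t, normalize=True)
    rng = np.random.default_rng(4)
    t = TensorField2D(rng.standard_normal((6, 5, 5)))
    iso = isotropic_stress(t, normalize=True, convention="abs")
    assert np.abs(iso.values).max() == pytest.approx(1.0)
    assert iso.normalization is not None


def test_out_of_plane_stress_extraction():
    assert np.allclose(out_of_plane_stress(_tensor([1, 2, 5, 0, 0, 0])).values, 5.0)
    assert np.allclose(out_of_plane_stress(_tensor([3, -1, 0, 2, 0, 0])).values, 0.0)
    rng = np.random.default_rng(5)
    t = TensorField2D(rng.standard_normal((6, 6, 6)))
    assert np.array_equal(out_of_plane_stress(t).values, t.comp("zz"))


def test_max_inplane_shear_values_and_rotation_invariance():
    assert np.allclose(max_inplane_shear(_tensor([3, 1, 0, 0, 0, 0])).values, 1.0)
    assert np.allclose(max_inplane_shear(_tensor([0, 0, 0, 0.7, 0, 0])).values, 0.7)
    rng = np.random.default_rng(6)
    t = TensorField2D(rng.standard_normal((6, 5, 5)))
    tau = max_inplane_shear(t).values
    # rotate the in-plane block by a random angle and recompute
    th = 0.83
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, -s], [s, c]])
    xx, yy, xy = t.comp("xx"), t.comp("yy"), t.comp("xy")
    rot = np.empty_like(t.components)
    for i in range(5):
        for j in range(5):
            M = R @ np.array([[xx[i, j], xy[i, j]], [xy[i, j], yy[i, j]]]) @ R.T
            rot[0, i, j], rot[1, i, j], rot[3, i, j] = M[0, 0], M[1, 1], M[0, 1]
    rot[2], rot[4], rot[5] = t.components[2], t.components[4], t.components[5]
    tau_rot = max_inplane_shear(TensorField2D(rot)).values
    assert np.allclose(tau, tau_rot, atol=1e-10)


# ------------------------------------------------------------- fluctuations

def test_susceptibility_values_and_oracle():
    assert susceptibility(ScalarField2D(np.full((3, 3), 2.5))) == pytest.approx(0.0)
    f = ScalarField2D(np.array([[1.0, 1.0], [-1.0, -1.0]]))
    assert susceptibility(f) == pytest.approx(4.0)
    rng = np.random.default_rng(7)
    v = rng.standard_normal((11, 13))
    # two-pass loop oracle
    m = sum(float(x) for x in v.ravel()) / v.size
    var = sum((float(x) - m) ** 2 for x in v.ravel()) / v.size
    assert susceptibility(ScalarField2D(v)) == pytest.approx(v.size * var, rel=1e-10)


def test_field_statistics_sweep_contract():
    f = ScalarField2D(np.array([[1.0, 2.0], [3.0, 4.0]]))
    tab = field_statistics_sweep({0.2: f, 0.4: f, 0.3: f}, reference=0.2)
    assert list(tab["control"]) == [0.2, 0.3, 0.4]     # strictly increasing
    assert np.allclose(tab["mean_norm"], 1.0)           # identical fields
    assert np.allclose(tab["chi_norm"], 1.0)
    with pytest.raises(ValueError, match="reference"):
        field_statistics_sweep({0.2: f}, reference=0.5)
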