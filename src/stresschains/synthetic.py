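"""Synthetic inputs for every stage of the pipeline.

These generators stand in for raw simulation output so the analysis chain is
testable end to end: i.i.d. continuous fields (whose percentile thresholding
is exactly site percolation), spectrally correlated Gaussian fields (the
long-range-correlated contrast case), toy dipole "stress chain" fields,
exact-scaling-law percolation curve sets (the collapse oracle), and
desk-scale monolayer configurations on either side of the solid/liquid
transition.  Every generator is bitwise deterministic given (spec, seed).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .fields import ScalarField2D
from .monolayer import MonolayerState, init_monolayer
from .params import ModelParams
from .percolation import PercolationCurves

__all__ = [
    "iid_uniform_field",
    "gaussian_correlated_field",
    "dipole_chain_field",
    "scaling_curve_set",
    "monolayer_fixture",
]


def iid_uniform_field(shape: tuple[int, int], seed: int | None = None,
                      rng: np.random.Generator | None = None) -> ScalarField2D:
    """I.i.d. Uniform(0,1) field — the random-percolation null case."""
    if min(shape) < 2:
        raise ValueError("field shape must be at least 2x2")
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = rng.random(shape)
    return ScalarField2D(values=vals, kind="other",
                         metadata={"kind": "iid_uniform", "seed": seed})


def gaussian_correlated_field(shape: tuple[int, int], spectral_exponent: float,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None) -> ScalarField2D:
    """Gaussian field with power spectrum |q|^(-spectral_exponent).

    Spectral synthesis: FFT of white noise filtered by |q|^(-exponent/2)
    (Hermitian symmetry holds automatically for the transform of a real
    field, so the output is exactly real); the DC mode is zeroed and the
    field standardized to unit variance.  Exponent 0 is white noise.
    """
    if not np.isfinite(spectral_exponent) or spectral_exponent < 0:
        raise ValueError("spectral exponent must be finite and >= 0")
    if min(shape) < 2:
        raise ValueError("field shape must be at least 2x2")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    qx = np.fft.fftfreq(shape[0])[:, None]
    qy = np.fft.fftfreq(shape[1])[None, :]
    q = np.sqrt(qx**2 + qy**2)
    with np.errstate(divide="ignore"):
        filt = np.where(q > 0, q ** (-spectral_exponent / 2.0), 0.0)
    vals = np.fft.ifft2(np.fft.fft2(white) * filt).real
    vals -= vals.mean()
    sd = vals.std()
    if sd > 0:
        vals /= sd
    return ScalarField2D(values=vals, kind="other",
                         metadata={"kind": "gaussian_correlated",
                                   "spectral_exponent": spectral_exponent,
                                   "seed": seed})


def dipole_chain_field(shape: tuple[int, int], n_chains: int,
                       amplitude: float = 1.0,
                       orientation_spread: float = 0.2,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> ScalarField2D:
    """Filamentary field of alternating compressive/tensile ridges.

    Each chain is an anisotropic Gaussian ridge (long axis along the chain
    orientation) with sign alternating between chains, emulating the stringy
    high-|stress| patterns of an active monolayer; the field mean is removed.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    nx, ny = shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    vals = np.zeros(shape)
    length = 0.35 * max(nx, ny)
    width = max(1.5, 0.02 * max(nx, ny))
    for c in range(n_chains):
        cx = rng.uniform(0, nx)
        cy = rng.uniform(0, ny)
        ang = rng.normal(0.0, orientation_spread) if c % 2 == 0 else \
            rng.normal(math.pi / 2, orientation_spread)
        ca, sa = math.cos(ang), math.sin(ang)
        dx = x - cx
        dy = y - cy
        # minimum image so ridges wrap the periodic box
        dx = dx - nx * np.round(dx / nx)
        dy = dy - ny * np.round(dy / ny)
        u = ca * dx + sa * dy       # along the chain
        v = -sa * dx + ca * dy      # across
        sign = 1.0 if c % 2 == 0 else -1.0
        vals += sign * amplitude * np.exp(-(u / length) ** 2 - (v / width) ** 2 / 2.0)
    vals -= vals.mean()
    return ScalarField2D(values=vals, kind="other",
                         metadata={"kind": "dipole_chain", "n_chains": n_chains,
                                   "amplitude": amplitude, "seed": seed})


def _master_P(x: np.ndarray) -> np.ndarray:
    """Smooth increasing master function for the spanning density."""
    return 1.0 / (1.0 + np.exp(-x))


def _master_S(x: np.ndarray) -> np.ndarray:
    """Smooth positive bump master function for the cluster size."""
    return 0.1 + np.exp(-0.5 * x**2)


def _master_Pi(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-4.0 * x))


def scaling_curve_set(pc: float, beta: float, nu: float, gamma: float,
                      ells, p_grid, noise: float = 0.0,
                      n_realizations: int = 10,
                      seed: int | None = None) -> PercolationCurves:
    """Percolation curves generated exactly from the scaling forms.

    P(p,l) = l^(-beta/nu) F((p-pc) l^(1/nu)) and
    S(p,l) = l^(gamma/nu) G(...) for fixed smooth master functions F
    (logistic) and G (Gaussian bump + offset), with multiplicative
    log-normal noise of relative strength ``noise`` per realization.  The
    generator parameters are embedded in the metadata for recovery tests.
    """
    if beta < 0 or gamma <= 0 or nu <= 0:
        raise ValueError("exponents must be positive (beta may be 0)")
    ells = sorted(int(e) for e in ells)
    if len(ells) < 3:
        raise ValueError("need at least 3 sizes")
    p = np.asarray(p_grid, dtype=float)
    rng = np.random.default_rng(seed)

    P, S, xi, Pi = {}, {}, {}, {}
    for ell in ells:
        x = (p - pc) * ell ** (1.0 / nu)
        baseP = ell ** (-beta / nu) * _master_P(x)
        baseS = ell ** (gamma / nu) * _master_S(x)
        basePi = _master_Pi(x)
        base_xi = 0.3 * ell * _master_S(x) / _master_S(np.zeros(1))[0]
        def noisy(base):
            reps = np.tile(base, (n_realizations, 1))
            if noise > 0:
                eta = rng.standard_normal(reps.shape)
                reps = reps * np.exp(noise * eta - 0.5 * noise**2)
            return reps
        P[ell] = noisy(baseP)
        S[ell] = noisy(baseS)
        xi[ell] = noisy(base_xi)
        Pi[ell] = np.clip(noisy(basePi), 0.0, 1.0)

    return PercolationCurves(
        p=p, ells=ells, P=P, S=S, xi=xi, Pi=Pi,
        metadata={"kind": "scaling_curves", "pc": pc, "beta": beta,
                  "nu": nu, "gamma": gamma, "noise": noise, "seed": seed},
    )


#: Dimensionless drives per fixture regime: low adhesion + low traction is
#: deep in the solid (caged) state; high adhesion + high traction is liquid.
REGIME_DRIVES = {"solid_like": (0.1, 0.2), "liquid_like": (0.5, 0.8)}


def monolayer_fixture(N: int = 16, regime: str = "solid_like",
                      seed: int = 0, R0: float = 5.0,
                      grid: tuple[int, int, int] | None = None,
                      n_sim: int = 2000) -> tuple[ModelParams, MonolayerState]:
    """Desk-scale monolayer configuration on one side of the transition.

    Returns ready-to-run (params, initial state).  The box is sized so the
    confluent triangular packing has nearest-neighbour spacing ~ 2 R0.  The
    two regimes differ only in the dimensionless drives (omega_tilde,
    alpha_tilde); all numerics are identical.
    """
    if regime not in REGIME_DRIVES:
        raise ValueError(f"regime must be one of {sorted(REGIME_DRIVES)}")
    if N > 64:
        warnings.warn(f"N={N} exceeds the desk-scale profile (<= 64 cells)")
    if grid is None:
        cols = max(2, int(round(math.sqrt(N))))
        rows = max(2, N // cols + (N % cols > 0))
        Lx = int(round(cols * 2 * R0))
        Ly = int(round(rows * 2 * R0 * math.sqrt(3) / 2))
        grid = (Lx, Ly, int(math.ceil(2.0 * R0 + 10.0)))
    omega_t, alpha_t = REGIME_DRIVES[regime]
    params = ModelParams(N=N, R0=R0, grid=grid, seed=seed, n_sim=n_sim,
                         lam=2.0, dtype="float32").with_drives(
                             omega_tilde=omega_t, alpha_tilde=alpha_t)
    params.check()
    state = init_monolayer(params, np.random.default_rng(seed))
    return params, state
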