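"""Random-percolation validation of the percolation/FSS stage.

Percentile-thresholding an i.i.d. continuous field at occupation p is
exactly site percolation, so running the full pipeline on i.i.d. uniform
fields must recover the 2D random-percolation universality class:
pc = 0.5927, nu = 4/3, beta = 5/36 ~ 0.1388, gamma = 43/18 ~ 2.389 for
nearest-neighbour site percolation on the square lattice.  This module runs
that study end to end (generate -> threshold -> label -> curves -> crossing
-> collapse) and reports the estimates with bootstrap errors.
"""

from __future__ import annotations

import numpy as np

from .fss import fss_collapse_joint, spanning_probability_crossing
from .percolation import percolation_curves
from .synthetic import iid_uniform_field

__all__ = ["random_percolation_study", "RP2D_REFERENCE"]

#: Literature exponents of 2D random (site) percolation on the square lattice.
RP2D_REFERENCE = {"pc": 0.5927, "nu": 4.0 / 3.0, "beta": 5.0 / 36.0,
                  "gamma": 43.0 / 18.0}


def random_percolation_study(seed: int = 0,
                             sizes: tuple[int, ...] = (64, 128, 256),
                             n_realizations: int = 200,
                             p_min: float = 0.50, p_max: float = 0.70,
                             p_step: float = 0.005,
                             connectivity: str = "face4",
                             n_bootstrap: int = 50) -> dict:
    """Estimate (pc, nu, beta, gamma) from i.i.d. uniform random fields.

    For each characteristic length ``l`` in ``sizes``, ``n_realizations``
    independent (l+1)^2-site fields are generated, thresholded over the p
    grid, and measured; pc comes from the spanning-probability crossings
    refined by the P-collapse, nu and beta from the P-collapse, gamma from
    the S-collapse.  Returns a dict with estimates, bootstrap errors and the
    collapse qualities.
    """
    root = np.random.default_rng(seed)
    p_grid = np.arange(p_min, p_max + 0.5 * p_step, p_step)

    curves_by_ell = {}
    for ell in sizes:
        rng = np.random.default_rng(root.integers(2**31))
        fields = (iid_uniform_field((ell + 1, ell + 1), rng=rng)
                  for _ in range(n_realizations))
        c = percolation_curves(fields, p_grid, ells=None,
                               connectivity=connectivity)
        curves_by_ell[ell] = c

    # merge the per-size ensembles into one curve container
    from .percolation import PercolationCurves
    merged = PercolationCurves(
        p=p_grid, ells=sorted(sizes),
        P={e: curves_by_ell[e].P[e] for e in sizes},
        S={e: curves_by_ell[e].S[e] for e in sizes},
        xi={e: curves_by_ell[e].xi[e] for e in sizes},
        Pi={e: curves_by_ell[e].Pi[e] for e in sizes},
        connectivity=connectivity,
        metadata={"kind": "iid_uniform_ensembles",
                  "n_realizations": n_realizations, "seed": seed},
    )

    pc_cross, pc_cross_err = spanning_probability_crossing(
        merged, n_bootstrap=n_bootstrap, rng=np.random.default_rng(root.integers(2**31)))

    # joint P+S collapse with shared (pc, 1/nu): the two observables carry
    # finite-size corrections of opposite sign in 1/nu at these sizes, so
    # the combined objective is the better-conditioned estimator
    fit = fss_collapse_joint(merged, pc0=pc_cross, n_bootstrap=n_bootstrap,
                             seed=int(root.integers(2**31)))

    return {
        "curves": merged,
        "pc_crossing": pc_cross, "pc_crossing_err": pc_cross_err,
        "fit": fit,
        "pc": fit.pc, "pc_err": fit.pc_err,
        "nu": fit.nu, "nu_err": fit.nu_err,
        "beta": fit.beta, "beta_err": fit.beta_err,
        "gamma": fit.gamma, "gamma_err": fit.gamma_err,
        "reference": dict(RP2D_REFERENCE),
    }
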