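# Methods

## Model

A confluent monolayer of `N` cells rests on a rigid substrate (normal
`e_z`), with periodic boundaries in the substrate plane.  Cell `i` is a 3D
phase field `phi_i(x, t)` (1 inside, 0 outside, tanh interface of width
`lam`) evolved by relaxational (Model A) dynamics with self-advection,

    d phi_i/dt + v_i . grad phi_i = -Gamma dF/dphi_i .

The free energy has, per cell: a double-well `4 phi^2 (1-phi)^2` plus
square-gradient term (coefficient `c_bulk = E lam / 2`), a soft volume
constraint `mu (1 - V_i/V0)^2` with `V_i = int phi_i^2` and
`V0 = (4/3) pi R0^3`, overlap repulsions `phi_i^2 phi_j^2` against other
cells (`c_rep_cc = kappa_cc / lam`) and the wall field
(`c_rep_cw = kappa_cw / lam`), and gradient adhesions
`grad phi_i . grad phi_j` (`c_adh_cc = omega_cc lam^2`,
`c_adh_cw = omega_cw lam^2`).  The printed typography of these prefactors
admits more than one reading, so each coefficient is independently
configurable (`c_*` overrides); the defaults above are the convention used
throughout.  Pair sums run over ordered pairs, so each unordered pair
contributes twice; the functional derivative carries the matching factors
and is held consistent with the discrete energy (see *Numerics*).

Overdamped force balance closes the loop: the passive traction

    T_i = int (dF/dphi_i) grad phi_i dx

is the force the free-energy landscape exerts on cell `i` (sign chosen so
that passive motion descends the free energy — repulsion pushes overlapping
cells apart; see *Sign conventions*), and

    xi v_i = T_i + alpha p_i ,    p_i = (cos theta_i, sin theta_i, 0).

Polarity follows contact inhibition of locomotion: `theta_i` relaxes toward
the direction of the in-plane cell–cell interaction force (the `kappa_cc`
and `omega_cc` part of the traction) at rate `|T_int,xy| / tau_pol`, plus
rotational noise `Dr sqrt(dt) eta` with `eta ~ N(0,1)`.  Two deliberate
readings here:

* the noise amplitude is literally `Dr` (not `sqrt(2 Dr)`), as the dynamics
  is written; the alternative is a reparametrization of `Dr`.
* the drive uses the *interaction* traction projected in-plane, not the full
  traction.  The full vector is dominated by substrate-normal forces and by
  self-drag of the moving interface, which carry no information about cell
  contacts; feeding them into the alignment produced an unphysical global
  flocking lock-in of the whole desk-scale crystal.  "Interaction force"
  is read as the cell–cell part.

The two dimensionless drives are `omega_tilde = omega_cc/omega_cw`
(adhesion ratio, studied in [0.1, 0.5]) and
`alpha_tilde = alpha tau_pol / (xi R0)` (active traction, [0, 0.8]).
Confluence is maintained trivially: no proliferation, no extrusion; a
monitor flags any cell whose `int phi^2` falls below half of `V0`.

## Numerics

* Grid: uniform lattice, spacing `a0 = 1`; fields periodic in x/y,
  zero-flux in z.  The substrate is a static tanh profile occupying
  `z < z_wall`.  The box must leave headroom `>= z_wall + 2 R0 + 2 lam` in
  z: a shorter box lets the zero-flux top boundary act as an attracting
  mirror image and peels the layer off the substrate (this is validated at
  construction).
* Every cell field lives on the full grid.  A cell-local moving-subdomain
  scheme would save memory at publication scale but is unnecessary at desk
  scale, so it was not built.
* Discrete consistency: the gradient-type energy terms are discretized with
  *face differences* (sums of squared forward differences), whose exact
  variation is the 7-point Laplacian used in the functional derivative.
  With central differences instead, the energy and its derivative are only
  consistent to O(a0^2) and the finite-difference oracle (1e-4 relative)
  fails.  Tractions use central-difference gradients (no adjointness
  needed).
* Time stepping: explicit Euler, first-order upwind advection with the
  cell's rigid-body velocity, Euler–Maruyama for the polarity angle with
  the drift factor capped at 1 (no over-rotation).  A CFL guard aborts when
  `max|v| dt / a0 > 0.4`.  `dt = 0.03` is stable for the shipped
  coefficients (the stiffest term is the interface diffusion
  `Gamma c_bulk lam^2`).
* `phi` is clamped to [0, 1] after each step.  Clamp events are counted;
  only overshoots beyond 1e-9 are logged as events.  Note that a constant
  clamp rate at the substrate interface is expected: the wall-adhesion term
  contributes to `dF/dphi_i` even where `phi_i = 0`, and the projection
  onto [0, 1] is what enforces positivity there.
* Cells are seeded as tanh spheres with radius inflated by `lam/4`, which
  makes `int phi^2` match `V0` to leading order in `lam/R0` (the interface
  deficit of `phi^2` is `lam/4` per unit area).
* Centroids are tracked by the circular mean of `phi^2` in the periodic
  plane and unwrapped by minimum-image increments, so trajectories are
  continuous across the boundaries.
* Desk-scale runs store fields in float32 (`dtype` parameter); all oracle
  and invariant tests run in float64.

### Sign conventions

The traction is stored with the sign under which overdamped passive motion
descends the free energy; a rigid-translation finite-difference experiment
fixes this sign unambiguously (with the opposite choice, overlapping cells
would attract).  Nodal tractions are the forces *experienced* by cells
(reaction convention); under the dyadic coarse-graining below, a repulsive
cell–cell contact then carries *negative* (compressive) isotropic stress
and adhesive contacts positive (tensile), matching the granular
force-chain picture.

## Default parameters

All in lattice units; every value is overridable.  The supplementary
parameter table of the source study is not available, so these defaults are
the package's own calibration, chosen once to produce (i) a stable
confluent layer that relaxes without losing cells, (ii) visible caging in
the low-drive regime and visible neighbour rearrangement at the top of the
drive ranges, at desk scale (N <= 16, box ~ 40 x 35 x 20).

| parameter | default | role |
|---|---|---|
| `R0` | 8 (5 in desk fixtures) | initial cell radius |
| `lam` | 2 | interface width (>= 2 a0 to resolve the interface) |
| `E` | 0.08 | interface stiffness |
| `mu` | 2000 | volume-constraint strength; the equilibrium volume deficit scales like `E lam R0^3 / mu`, so `mu` must grow with cell volume to hold the deficit at a few percent |
| `kappa_cc` | 0.02 | cell–cell repulsion (soft enough for squeeze-past events) |
| `kappa_cw` | 0.5 | keeps cells from penetrating the substrate |
| `omega_cw` | 0.02 | substrate adhesion (holds the layer down) |
| `Gamma` | 1 | interface mobility (sets the time unit) |
| `xi_fric` | 5 | substrate friction; overdamps the z-settling transient |
| `tau_pol` | 4 | polarity alignment time; liquid-regime mixing in cell diameters is `alpha_tilde t / (2 tau_pol)`, so a short alignment time is what makes desk-scale melting observable |
| `Dr` | 0.6 | rotational noise; makes single-cell direction decorrelate in ~ 3 time units so activity does not order into a global flock |
| `dt` | 0.03 | explicit-Euler step |

The desk fixtures (`monolayer_fixture`) place `N` cells on a jittered
triangular packing with nearest-neighbour spacing ~ `2 R0` (confluence) and
differ between regimes only in the drives: `(omega_tilde, alpha_tilde)` =
(0.1, 0.2) for `solid_like`, (0.5, 0.8) for `liquid_like`.

## Stress fields

Per-node tractions collect every cell's passive density
`(dF/dphi_i) grad phi_i` plus its active force density, distributed
proportionally to `phi_i^2` and normalized so the cell integral recovers
`alpha p_i` exactly.  The coarse-grained stress on the complementary (dual)
lattice is `sigma = (1/a0^3) sum_j r_ij (x) T_j` with the neighbour set
`N_i` = the 8 corner nodes of the dual cell at `(i+1/2, j+1/2, k+1/2)`; the
z-column is summed to give the 2D analysis field.  A purely in-plane
4-neighbour stencil is available (`face4`) but makes all out-of-plane
components vanish identically, which would forbid the `sigma_zz` analysis;
the 8-corner dual is therefore the default.  The dyadic product is not
symmetric and is symmetrized on construction.  Scalar reductions: isotropic
stress `(1/3) tr sigma` (normalized by maximum compression by default, or by
maximum magnitude), out-of-plane `sigma_zz`, and maximum in-plane shear
`sqrt(((sxx-syy)/2)^2 + sxy^2)`.  The susceptibility of a field is
`chi = n (<x^2> - <x>^2)` with `n` the number of lattice sites (extensive
convention, configurable in principle by multiplying back).

## Structure diagnostics

`g(r)` is the in-plane pair correlation of cell centroids with
minimum-image distances, bin width `R0/20`, `r_max = min(box)/2`,
normalized so a Poisson configuration gives `g ~ 1`.  Two configurational
averages are offered: the correlation of *time-averaged positions* (each
cell's centroid averaged over the production window; solid: sharp lattice
peak at `r/R0 ~ 2`; deep liquid: mean positions of different cells overlap
and weight collapses far below the diameter), and the *time-averaged
instantaneous* correlation (the bracket in the definition read as the time
average).  The classifier smooths g with a 3-bin moving average, excludes
the self-overlap region `r/R0 < 0.2`, finds local maxima above 1.05x the
baseline and labels solid if the dominant peak lies in [1.6, 2.4] (one
cell diameter), liquid if it lies below 1.2, otherwise indeterminate.  The
static structure factor is evaluated on the allowed wavevectors of the
periodic box, `S(q) = |sum_j exp(i q r_j)|^2 / N` (raw, not windowed).

## Percolation and finite-size scaling

Thresholding: sites with field value strictly above the `(1-p)`-quantile
(linear-interpolation percentile) are occupied; on an i.i.d. continuous
field this is exactly site percolation at occupation `p` (fixed occupation
number, i.e. the microcanonical ensemble).  `p = 1` is special-cased to
full occupation (the strict rule would exclude the minimum).  A constant
field raises a degenerate-tie error.  Clusters are connected components
under 4- (`face4`, default) or 8-neighbour (`moore8`) connectivity;
spanning means touching both opposite edges in either axis (open
boundaries).  Observables per subsystem: spanning density `P` (spanning
sites over all sites), second-moment cluster size
`S = sum s^2 n_s / sum s n_s` excluding spanning clusters (the definition
under which `S ~ |p - pc|^-gamma`; plain mean available), correlation
length `xi^2 = sum 2 Rg^2 s^2 n_s / sum s^2 n_s` (equals the s^2-weighted
mean squared same-cluster pair distance), and the spanning indicator `Pi`.
Subsystems of `(l+1)^2` sites are tiled without overlap and each is
thresholded against its own value distribution.

The scaling ansatz `P = l^(-beta/nu) F((p-pc) l^(1/nu))`,
`S = l^(gamma/nu) G(...)` is fitted by minimizing a master-curve objective:

* default: Houdayer–Hartmann-style quality — for each scaled point, a
  local *quadratic* fit through the nearest points of the other sizes
  (uniform fit weights; the residual is normalized by the point error plus
  the propagated master error).  Quadratic local fits keep the curvature
  bias of the master at O(h^3); with linear fits the recovered exponents
  acquire visible bias on fine grids.  Saturated points (zero sample
  variance, e.g. `Pi` identically 0/1 in the tails) are excluded: they
  carry no information and otherwise dilute the objective, biasing `1/nu`
  low.
* "spline" mode: cubic-spline interpolation residual, which vanishes on
  exact-scaling data; used by the generator self-tests.

The fit window keeps points with `|p - pc0| <= w l^(-0.75)` (w = 2 by
default) around the crossing-based `pc0`, so the point set is fixed during
optimization.  Nelder–Mead with multi-start; box constraints keep `pc`
within +-0.03 of `pc0` and the exponent ratios in generically sane ranges,
because the collapse objective has a degenerate ray at extreme ratios
(off-critical curves are nearly size-independent).  `pc` is initialized
from pairwise crossings of `Pi(p, l)` (linear interpolation, root nearest
the half-height point; scatter + bootstrap spread as its error).

At desk-scale sizes (l <= 256) the `P`- and `S`-collapses carry
finite-size corrections of *opposite sign* in `1/nu` (P alone prefers
`nu ~ 1.5-1.6`, S alone `~ 1.25`).  The validation study therefore uses the
joint collapse — shared `(pc, 1/nu)`, separate amplitudes `beta/nu` and
`gamma/nu`, objective `q_P + q_S` — which balances the two biases; both
single-observable modes remain available.  Errors come from bootstrap
resampling of whole realizations (not subsystems within a realization),
re-optimizing from the point estimate.

## Synthetic data

* `iid_uniform_field` — the random-percolation null; thresholding it *is*
  site percolation.
* `gaussian_correlated_field` — spectral synthesis with power spectrum
  `|q|^-theta` (real by construction, DC mode zeroed, unit variance): the
  long-range-correlated contrast case.
* `dipole_chain_field` — alternating-sign anisotropic Gaussian ridges, a
  minimal filamentary stand-in for stress chains.
* `scaling_curve_set` — curves generated exactly from the scaling forms
  with fixed smooth masters (logistic F, Gaussian-bump + offset G,
  steepened logistic for Pi) and multiplicative log-normal noise; the
  generator parameters ride along as metadata, making collapse recovery a
  closed loop.
* `monolayer_fixture` — the desk-scale initial conditions described above.

What the generators do *not* emulate: correlations between P and S noise
within a realization, corrections to scaling (the curve set is exactly
scale-invariant), and any spatial structure of real stress fields beyond
the two covered correlation classes.  Passing the recovery tests therefore
shows the estimator is consistent and unbiased on clean scaling data, and
the i.i.d. study shows the whole chain reproduces known universality — it
does not by itself certify exponents measured on simulation stress fields
at publication scale.

## Study sizes

The validation study uses 200 independent fields per size
`l in {64, 128, 256}` with a p-grid of step 0.005 on [0.50, 0.70], and
bootstrap sizes of a few tens; desk-scale monolayer runs use N = 16 cells
(40 x 35 x 20 boxes) for 2000 steps (solid) and 10000 steps (liquid), and
N = 9 for the drive sweeps.
These sizes were chosen so the full chain remains a desk-scale computation;
the publication-scale sweep (400 cells, 321^2 analysis lattice, subsystems
l in [20, 100], three realizations per drive value) is expressible as a
pipeline config and validated as such, but running it is cluster-scale
work and its exponents are expected to carry larger corrections than the
synthetic-field study.

## Known limitations

* Desk-scale liquefaction needs long runs: the sub-diameter signature of
  the liquid regime (mean positions of different cells overlapping) builds
  up over ~10^4 steps at N = 16; shorter liquid runs classify as
  indeterminate rather than liquid.
* Explicit Euler limits `dt`; stiff parameter corners (strong wall
  adhesion) hit the CFL guard rather than silently diverging.
* The stress lattice convention (8-corner dual) is one defensible reading
  of a construction whose exact definition lives in unavailable
  supplementary material; the stencil is pluggable.
* `Dr` enters as written (amplitude), so literature values quoted as
  diffusivities must be converted.
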