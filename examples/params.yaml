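N: 16
R0: 5.0
grid:
- 40
- 35
- 20
a0: 1.0
z_wall: 3.0
E: 0.08
mu: 2000.0
lam: 2.0
kappa_cc: 0.02
kappa_cw: 0.5
omega_cc: 0.002
omega_cw: 0.02
Gamma: 1.0
xi_fric: 5.0
alpha: 1.25
tau_pol: 4.0
Dr: 0.6
dt: 0.03
n_sim: 2000
seed: 1
cfl_max: 0.4
dtype: float32
c_bulk: null
c_rep_cc: null
c_rep_cw: null
c_adh_cc: null
c_adh_cw: null
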