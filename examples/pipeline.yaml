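seed: 1
stages:
- synth
- percolate
- collapse
- report
synth:
  kind: iid
  shape:
  - 65
  - 65
  n_fields: 100
percolate:
  p_min: 0.5
  p_max: 0.7
  p_step: 0.005
  ells:
  - 16
  - 32
  - 64
  connectivity: face4
collapse:
  observables:
  - P
  - S
  n_bootstrap: 50
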