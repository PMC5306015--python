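# Shipped demo: simulated 73-site study with the documented strong per-group
# effects; two response groups by two modes, spline correlograms on model
# residuals. Deterministic given the seed.
seed: 73
groups: [all, woodland]
modes: [spatial_T0, temporal]
sim:
  n_sites: 73
  grid_size: 45
  cell_size: 50.0
  aggregation: 60.0
effects: strong
correlogram_B: 200
make_plots: true
stage2_cap: 20
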