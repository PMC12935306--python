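# Default two-strain biofilm competition configuration (qr simulate / qr sweep).
# Units are nondimensional: time in strain-1 growth time scales (r1 = 1),
# length relative to the domain radius, densities relative to carrying
# capacity. B2's growth-rate advantage of 1.3 reproduces the rapid-dominance
# regime; set r: 1.0 for the coexistence control.
grid:
  nx: 256          # grid resolution (nx x nx)
  radius: 30.0     # disc domain radius
strains:
  - {name: B1, r: 1.0, d: 1.0}
  - {name: B2, r: 1.3, d: 1.0}
layout:
  n_per_strain: 25     # founder spots per strain (1:1 mixed inoculum)
  inoculum_radius: 5.0
  spot_radius: 0.8
  b0: 0.5              # founder density per spot
  seed: 11
# dt defaults to half the explicit-scheme stability bound h^2/(4 max d)
t_end: 50.0
coverage_stop: 0.90    # stop once 90% of the domain is occupied
occupancy_threshold: 0.05
snapshot_every: 10.0
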