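"""Two-strain colony competition: how a small growth-rate difference decides
the outcome.

Builds a disc-shaped domain seeded with a 1:1 mixed inoculum, runs the
two-strain biofilm model at equal growth rates and with a 1.3x advantage for
strain B2, and sweeps the relative growth rate. The final relative densities
f1/f2 are each strain's share of total biomass; 0.5/0.5 means coexistence,
values near 0/1 mean competitive exclusion.
"""

from quorumcomp.biofilm import (SimGrid, SimulationConfig, StrainParams,
                                make_founder_layout, mirrored_layout,
                                simulate, sweep_relative_growth)

grid = SimGrid.disc(radius=15.0, nx=128)

# equal growth rates, exactly mirror-symmetric inoculum: coexistence at 50/50
equal = (StrainParams("B1", r=1.0, d=1.0), StrainParams("B2", r=1.0, d=1.0))
layout = mirrored_layout(15, inoculum_radius=4.0, spot_radius=0.7, b0=0.5,
                         seed=11)
res = simulate(SimulationConfig(grid, equal, layout, t_end=50.0))
print(f"equal growth rates:   f1 = {res.outcome.f1:.3f}, "
      f"f2 = {res.outcome.f2:.3f}  (coexistence)")

# a 1.3x growth advantage for B2: rapid dominance of the mixed colony
fast = (StrainParams("B1", r=1.0, d=1.0), StrainParams("B2", r=1.3, d=1.0))
layout2 = make_founder_layout(15, 4.0, 0.7, 0.5, seed=11, grid=grid)
res2 = simulate(SimulationConfig(grid, fast, layout2, t_end=50.0))
print(f"1.3x advantage for B2: f1 = {res2.outcome.f1:.3f}, "
      f"f2 = {res2.outcome.f2:.3f}  (B2 dominates)")

# outcome as a function of the relative growth rate rho = r2/r1
base = SimulationConfig(grid, equal, layout2, t_end=50.0)
table = sweep_relative_growth(base, [0.8, 0.9, 1.0, 1.1, 1.2, 1.3])
print("\nrelative growth rate sweep (fixed layout):")
print(table.to_string(index=False))
print("\nf2_final rises steeply around rho = 1: small doubling-time "
      "differences translate into large shifts in the final strain ratio.")
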