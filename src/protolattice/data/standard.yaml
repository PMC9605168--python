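# Standard-case run configuration.
# Residual rates are fractions in [0, 1]; reaction/removal rates are percent.
lattice:
  width: 100
  height: 100
init:
  mol1_per_cell: 1000000
  mol6_per_cell: 50000
  mol7_per_cell: 50000
  mol12_per_cell: 100000
  mol14_per_cell: 3
  mol15_per_cell: 9
  seed_amount_mol2: 100
  seed_amount_mol3: 100
  seed_radius: 2
  polymer1_initial_count: 10
  polymer1_initial_w: 0.650
  polymer1_region_radius: 3
  p1_size: 100
residual_rates:
  mol1: 0.0
  mol2: 0.75
  mol3: 0.05
  mol4: 0.75
  mol5: 0.05
  mol6: 0.0
  mol7: 0.0
  mol8: 1.0
  mol9: 1.0
  mol10: 1.0
  mol11: 1.0
  mol12: 0.0
  mol13: 1.0
  mol14: 1.0
  mol15: 1.0
  poly1: 0.1
  poly2: 0.75
network:
  window_policy: single_pass
  stage_f_gate: mol13
  rates_percent:
    rate_2_4: 5
    rate_3_5: 2
    removal_4: 5
    removal_5: 5
    removal_10: 5
    removal_11: 5
    removal_13: 75
polymer:
  p1_size: 100
  p2_degradation_rate: 0.05
run:
  steps: 2000
  seed: 0
  ledger_every: 10
  report_every: 10
  snapshot_every: 0
  mask_threshold: 1
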