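# Canonical wild-type defaults for a simulated T-cell colony.
# Regulation parameters and decay rates of the six-species transcriptional
# network; site-transition rates of the 500-site Bcl11b regulatory region;
# generation-dependent division-time distributions; progenitor (ETP)
# starting state; 120 h colony horizon.
grn:
  p1: 0.10
  p2: 1.00
  p3: 5.00
  p4: 1.00
  p5: 1.50
  p6: 0.01
  p7: 0.50
  p8: 0.70
  p9: 0.50
  p10: 1.00
  p11: 0.20
  p12: 2.50
  p13: 2.60
  p14: 2.00
  p15: 1.00
  p16: 0.01
  gamma_R: 0.15   # h^-1
  gamma_T: 0.15
  gamma_G: 0.23
  gamma_P: 0.06
  gamma_X: 0.02
  kd_factors: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
epigenetic:
  k1: 0.28        # X-coupled closing
  k2: 0.20        # Notch-coupled opening
  k3: 0.20        # Runx1-coupled opening
  alpha: 0.002    # O -> I mediated by C
  beta: 0.002     # I -> C mediated by C
  gamma_m: 0.0005 # I -> O mediated by O
  delta: 0.0005   # C -> I mediated by O
  epsilon: 0.002  # I -> C mediated by I
  S: 500
  open_fraction_threshold: 0.75
division_times:   # [mean_h, sd_h] for generations 0,1,2,3,>=4
  - [34.0, 13.0]
  - [15.0, 5.0]
  - [13.0, 5.0]
  - [12.0, 4.0]
  - [12.0, 3.0]
initial_state:
  Runx1: 1
  Tcf7: 2
  Gata3: 1
  PU.1: 5
  X: 8
  Notch: 7
initial_region:
  closed: 500
  intermediate: 0
  open: 0
  total: 500
horizon: 120.0
record_trajectories: false
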