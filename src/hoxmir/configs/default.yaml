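# Calibrated default configuration of the Hoxa5/Hoxc8/mir-x model.
#
# The basal network (section `network`) is the miRNA-free wiring: RA drives
# hoxa5 transcription, FGF drives hoxc8 transcription, each mRNA activates
# its own protein, and Hoxc8 protein weakly represses hoxa5 transcription
# (the repression is asymmetric: Hoxa5 does not inhibit Hoxc8).  Parameters
# are calibrated so that, without mir-x, the Hoxa5 and Hoxc8 domains overlap
# near the boundary and the boundary is rough under morphogen noise; adding
# the consensus mir-x circuit (section `mirx_circuit`) sharpens and aligns
# the boundary.  See docs/methods.md for the calibration rationale.

network:
  species: [hoxa5_mRNA, hoxa5_protein, hoxc8_mRNA, hoxc8_protein, mir_x]
  sigma: 5.0
  gamma:
    hoxa5_mRNA: 5.0
    hoxa5_protein: 5.0
    hoxc8_mRNA: 5.0
    hoxc8_protein: 5.0
    mir_x: 0.5
  basal:
    hoxa5_mRNA: -1.39
    hoxa5_protein: -1.84
    hoxc8_mRNA: -0.0776
    hoxc8_protein: -5.0
    mir_x: 0.6
  edges:
    - {source: RA, target: hoxa5_mRNA, weight: 2.0}
    - {source: FGF, target: hoxc8_mRNA, weight: 1.0}
    - {source: hoxc8_protein, target: hoxa5_mRNA, weight: -0.12}
    - {source: hoxa5_mRNA, target: hoxa5_protein, weight: 2.0}
    - {source: hoxc8_mRNA, target: hoxc8_protein, weight: 10.0}

# The three consensus mir-x interactions at the default interaction strength.
mirx_circuit:
  strength: 1.0
  edges:
    - {source: RA, target: mir_x, weight: -1.0}
    - {source: hoxc8_protein, target: mir_x, weight: 1.0}
    - {source: mir_x, target: hoxa5_protein, weight: -1.0}

gradient:
  source_strength: [5.0, 5.0]   # RA, FGF
  degradation: [6.25, 69.44]     # 1/day
  diffusion: [1.0, 1.0]         # length^2/day
  domain_length: 1.0
  n_cells: 100

noise:
  frequency: 10.0   # 1/day
  amplitude: 0.3
  per_cell: true

tissue:
  n_cells: 100
  n_replicates: 50
  t_dev: 7.0
  dt: 0.01
  store_every: 0.1
  relax_tol: 1.0e-6
  relax_t_max: 100.0

differentiation:
  n_cells_group: 200
  ra_level: 1.2
  duration: 5.0
  day3_time: 1.0    # "Day 3" analogue: one day after RA onset (RA given on day 2)
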