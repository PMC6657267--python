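name: case2
description: >
  Drug administered in the circulatory system killing every circulating
  tumour cell that has acquired exactly two driver mutations, regardless of
  which genes (d all-zero, m_d_drug = 2).
provenance: >
  Compartment chain, driver genes, ordered blocks and the drug signature
  follow the published breast-to-bone case study. Kinetic amplitudes,
  support windows, alpha, r, capacity, initial population, drug time and
  horizon are calibrated to place the qualitative regimes at desk scale;
  they are not literature-derived.
compartments:
  labels: [breast, circulatory, bone]
  transition_matrix:
    - [0.0, 1.0, 0.0]
    - [0.0, 0.0, 1.0]
    - [0.0, 0.0, 1.0]
  n_secondary: 1
  required_drivers:
    breast: [EPCAM]
    circulatory: [CD47, CD44]
    bone: [MET]
ordered_mode: true
kinetics:
  alpha: 1.0
  r: 1.0
  amplitudes: {asym: 1.0, sym: 0.8, apop: 0.25, pass: 2.0}
  centers: {asym: 0.25, sym: 0.5, apop: 0.8}
  width: 1.0
  s_bar: 1.0
  driver_split_beta: 6.0
bounds: {m_d: 4, m_n: 20, m_m: 15, k: 3}
constraints:
  capacity: 20
  energy:
    e: {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}
    E_max: {2: 12.0}
simulation:
  initial_cells: 15
  t_end: 5.5
  record_dt: 0.25
  replicates: 30
  seed: 11002
drug:
  d: [0, 0, 0, 0]
  m_n: 0
  m_m: 0
  k: 2
  m_d: 2
  t: 4.0
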