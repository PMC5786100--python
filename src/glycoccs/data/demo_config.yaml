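# Packaged demonstration run: calibration and comparison on the study
# tables, plus a synthetic two-state ensemble and a planted H-bond fixture.
seed: 7
calibration:
  calibrants: builtin:calibrants_polyalanine.csv
  analytes: builtin:glycan_drift_times.csv
comparison:
  table: builtin:glycan_calculated_ccs.csv
  pairs: builtin:isomer_pairs.csv
synthetic_ensemble:
  n_frames: 60
  weight_a: 0.6
  rmsd_separation: 10.0
  noise_sigma: 0.1
  n_atoms: 20
clustering:
  threshold: 2.5
ccs:
  method: projection
  gas: He
  temperature: 300.0
  n_orientations: 80
  n_darts: 1500
hbonds:
  mimic: {core_length: 2, arm13_length: 3, arm16_length: 2, fucose: true}
  n_frames: 20
  planted:
    - {donor_residue: 2, acceptor_residue: 7, r_xy: 3.0, theta: 10.0, fraction: 0.8}
    - {donor_residue: 3, acceptor_residue: 4, r_xy: 3.2, theta: 20.0, fraction: 1.0}
  r_max: 3.5
  theta_max: 30.0
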