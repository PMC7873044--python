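# Minimal calibration case: a short rod with one 6-bead tail carrying a
# single planted square-well contact between rod bead 7 and the tail end.
# Used to validate planted-contact recovery (pipeline probability vs an
# independent calibration run) across a well-depth grid.
label: two-state-toy
ref_body: {n_beads: 10, curvature_radius: 40.0}
mobile_bodies: []
tails:
  - {length: 6, attach: 5}
bond_length: 3.8
bead_radius: 2.0
sticky_pairs:
  - {ref_bead: 7, partner_bead: 16, eps: 2.0, width: 8.0}
temperature_factor: 1.0
seed: 1234
n_steps: 200000
record_interval: 100
equil_steps: 5000
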