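# Rigid curved rod (40 beads) with two 15-bead flexible tails (C-terminus
# surrogates) tethered at the rod ends.  The last five beads of each tail
# carry negative charges and five mid-rod beads carry positive charges
# (screened Coulomb), plus one hydrophobic-like square well near each
# attachment point, emulating a tail whose interactions mix electrostatic
# attraction toward a basic patch with short-range sticking near the
# tether.
#
# Concatenated bead indexing: rod 1-40; tail T1 41-55; tail T2 56-70.
label: system2-like
ref_body: {n_beads: 40, curvature_radius: 40.0}
mobile_bodies: []
tails:
  - {length: 15, attach: 1}
  - {length: 15, attach: 40}
bond_length: 3.8
bead_radius: 2.0
sticky_pairs:
  - {ref_bead: 5, partner_bead: 45, eps: 2.0, width: 8.0}
  - {ref_bead: 36, partner_bead: 60, eps: 2.0, width: 8.0}
charges:
  values:
    18: 1.0
    19: 1.0
    20: 1.0
    21: 1.0
    22: 1.0
    51: -1.0
    52: -1.0
    53: -1.0
    54: -1.0
    55: -1.0
    66: -1.0
    67: -1.0
    68: -1.0
    69: -1.0
    70: -1.0
  strength: 2.0
  screening_length: 10.0
temperature_factor: 1.0
seed: 1234
n_steps: 60000
record_interval: 100
equil_steps: 4000
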