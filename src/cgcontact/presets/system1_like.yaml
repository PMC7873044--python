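# Rigid curved rod (BAR-dimer surrogate, 40 beads) with two compact 8-bead
# mobile bodies (PDZ surrogates) on 12-bead flexible linkers tethered at the
# rod ends.  A few square-well sticky pairs plant preferential contacts
# between attachment-proximal rod beads and mobile-body beads, emulating a
# mobile domain that dwells at preferred sites on the reference body.
#
# Concatenated bead indexing: rod 1-40; chain M1 linker 41-52, body 53-60;
# chain M2 linker 61-72, body 73-80.
label: system1-like
ref_body: {n_beads: 40, curvature_radius: 40.0}
mobile_bodies:
  - {n_beads: 8, linker_length: 12, attach: 1}
  - {n_beads: 8, linker_length: 12, attach: 40}
tails: []
bond_length: 3.8
bead_radius: 2.0
sticky_pairs:
  - {ref_bead: 4, partner_bead: 56, eps: 3.0, width: 8.0}
  - {ref_bead: 6, partner_bead: 57, eps: 2.0, width: 8.0}
  - {ref_bead: 37, partner_bead: 76, eps: 3.0, width: 8.0}
temperature_factor: 1.0
seed: 1234
n_steps: 60000
record_interval: 100
equil_steps: 4000
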