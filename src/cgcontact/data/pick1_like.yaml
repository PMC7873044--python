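# Synthetic PICK1-like dimer fixture.
#
# The region boundaries and the filler sequence here are PLAUSIBLE,
# PACKAGE-AUTHORED choices, not published facts: the source system's exact
# monomer length and domain boundaries are not printed anywhere we rely on.
# Functionally important residues (the PDZ/linker/BAR key-pair residues, the
# basic patch K251/K252/K257/K266/K268, the acidic stretch D380-D389 and the
# anchor residues L60/S130/T167/S262/D390) are pinned at their conventional
# positions inside an otherwise random filler sequence.
label: pick1-like-dimer
chains:
  - id: A
    sequence:
      - "CYWMYVTFNHIYYAVDGGTSTRYEPYSKVQGSSTACYHLWAQYCSICLDVCAMDAGHNKL"
      - "YYFLFAFIATEMEHVLSGHGYHHVPGLNTNISHIHDCEYWIFMRDAYNKTDMSLEWVLYN"
      - "NGCQKRWFPSKTANEHFSTADIILLRWWCVPRLGILNPLAEKWNCVTMQIVVYTKRWTYS"
      - "AYPGVHWSRPGFAPYEQEHNVFKVDAQHKFVFAIRDEERHESGPPHDPQKRYWVNMPQME"
      - "LDTNEGLYKGKKTLSYKFNDKSPALKDKIEQMKMATLKCYEKWAHMGPTHIFPRLTELNC"
      - "EFEHPVSDFVVHEYLFFLIARIQPNIVKDLHAFDQHSSQTMSTIYADCYCVDMQKSGCIT"
      - "HGHWQGFKGVCCKRRNDRSDDDDDDDDDDDRYQPWNIEQLMNADKMGQHDPWHTLY"
  - id: B
    sequence:
      - "CYWMYVTFNHIYYAVDGGTSTRYEPYSKVQGSSTACYHLWAQYCSICLDVCAMDAGHNKL"
      - "YYFLFAFIATEMEHVLSGHGYHHVPGLNTNISHIHDCEYWIFMRDAYNKTDMSLEWVLYN"
      - "NGCQKRWFPSKTANEHFSTADIILLRWWCVPRLGILNPLAEKWNCVTMQIVVYTKRWTYS"
      - "AYPGVHWSRPGFAPYEQEHNVFKVDAQHKFVFAIRDEERHESGPPHDPQKRYWVNMPQME"
      - "LDTNEGLYKGKKTLSYKFNDKSPALKDKIEQMKMATLKCYEKWAHMGPTHIFPRLTELNC"
      - "EFEHPVSDFVVHEYLFFLIARIQPNIVKDLHAFDQHSSQTMSTIYADCYCVDMQKSGCIT"
      - "HGHWQGFKGVCCKRRNDRSDDDDDDDDDDDRYQPWNIEQLMNADKMGQHDPWHTLY"
regions:
  - {label: N_TERM, chains: [A, B], start: 1, end: 17}
  - {label: PDZ, chains: [A, B], start: 18, end: 105}
  - {label: LINKER, chains: [A, B], start: 106, end: 111}
  - {label: LINKER_HELIX, chains: [A, B], start: 112, end: 120}
  - {label: LINKER, chains: [A, B], start: 121, end: 134}
  - {label: BAR, chains: [A, B], start: 135, end: 357}
  - {label: C_TERM, chains: [A, B], start: 358, end: 416}
special_sets:
  basic_patch: {chains: [A, B], local_indices: [251, 252, 257, 266, 268]}
  acidic_stretch: {chains: [A, B], local_indices: [380, 381, 382, 383, 384, 385, 386, 387, 388, 389]}
restrained_regions: [PDZ, BAR]
anchor_pairs:
  pdz_to_bar_linker: [60, 130]
  pdz_to_bar_tip: [60, 262]
  pdz_to_bar_center: [60, 167]
  pdz_to_cterm_acidic: [60, 390]
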