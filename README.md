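# cgcontact

Residue-level inter-domain contact dynamics for coarse-grained (Cα)
protein trajectories.

Multi-domain scaffolding proteins such as PICK1 — a dimer in which a PDZ
domain hangs from a rigid, banana-shaped BAR-domain dimer by an
intrinsically disordered linker, flanked by disordered termini — do not form
a single complex between their domains.  Their regulation lives in *contact
statistics*: which residue pairs touch, how often, for how long, and where
the mobile domains sit relative to the rigid core.  `cgcontact` computes
exactly those quantities from Cα-trace trajectories (multi-model PDB or a
tabular format), and ships a tethered-domain Monte Carlo generator with
planted, independently calibratable contact propensities so that every stage
of the analysis is verifiable against known ground truth.

## What it computes

* **Contacts** — residues *i, j* are in contact in a frame when their Cα
  distance satisfies *d*ᵢⱼ ≤ 8 Å (a distance of exactly 8 Å counts) and,
  within a chain, |*i* − *j*| ≥ 5; inter-chain pairs are always eligible.
  Contact probability is the percentage of pooled frames in contact;
  contact maps can be displayed as log₁₀(probability %) with an explicit
  floor for empty cells.
* **Lifetimes** — a contact event is a maximal run of consecutive
  in-contact frames within one trajectory (runs never span trajectory
  boundaries; boundary-touching events are flagged censored and included).
  Durations are reported in units of 10⁵ simulation steps:
  duration = frames × Δt_snapshot / 10⁵.
* **Key-pair tables** — top-N pairs between two regions ranked by
  probability (ties by mean lifetime), with residue-class interaction calls
  (hydrophobic / electrostatic / polar / mixed).
* **Geometry** — Kabsch (SVD) superposition with proper rotations, RMSD
  series fit on the rigid-core regions, radius of gyration
  R_g = √(⟨|rᵢ − r̄|²⟩), anchor-residue distance distributions with
  frequencies normalised to 1.
* **Mobile-domain positions** — per-frame centroids of each mobile-region
  copy expressed in the reference-body frame, clustered with seeded
  k-means; occupancy fractions are per-observation percentages and sum
  to 100%.
* **Synthetic data** — a rigid curved rod (BAR surrogate) carrying rigid
  compact bodies on freely-jointed linkers (PDZ surrogates) and/or bare
  tails (C-terminus surrogates), sampled by Metropolis Monte Carlo at unit
  kT with square-well "sticky" pairs and optional screened Coulomb terms.

## Worked example

```sh
python examples/contact_lifetimes.py
```

prints (abridged):

```
pair (7, 16): in contact in 30.8% of 1337 frames
independent calibration run: 30.2% (2635 frames) -> planted propensity is recovered
266 contact events (1 touch a trajectory boundary and are flagged censored)
lifetime 0.0015 +/- 0.0009 in units of 100,000 steps (each frame = 100 generator steps)
```

The preset plants a 2 kT square well between rod bead 7 and the tail end
(bead 16).  The analysis pipeline recovers the planted contact propensity
(30.8%) within sampling error of an independent, longer calibration run
(30.2%), and the event statistics show the short-lived, frequently re-formed
contacts characteristic of a flexible tether.  The other example scripts
cover contact maps and key-pair tables, mobile-domain position clustering,
and RMSD/R_g/distance distributions.

A YAML-driven command line covers the same pipeline end to end:

```sh
cgcontact all --config run.yaml --out results_dir --seed 1
```

writing TSV tables (contact map, top pairs, RMSD/R_g series and histograms,
distance histograms, cluster report) plus a `provenance.json`; every output
names the config hash that produced it, and reruns with the same config and
seed are byte-identical.

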