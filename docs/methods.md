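# Methods

## Scope and data model

`cgcontact` analyses ensembles of Cα-trace snapshots of a multi-chain,
multi-domain protein system.  A `Topology` annotates residues with a
1-based *concatenated* index running across chains in declaration order
(so, in a dimer of 357-residue protomers, index 608 is residue 251 of the
second protomer), a region label (`N_TERM`, `PDZ`, `LINKER`,
`LINKER_HELIX`, `BAR`, `C_TERM`, `OTHER`), named special residue sets, and
the set of regions treated as rigid cores.  A `Trajectory` is an ordered
list of frames plus the simulation-step interval between snapshots
(default 10,000 steps); a `TrajectoryEnsemble` keeps independent
trajectories separate so that no time-domain statistic ever crosses a
trajectory boundary.  Coordinates are Å everywhere.

The shipped PICK1-like topology fixtures use *plausible* domain boundaries
and a synthetic filler sequence with the functionally named residues (the
basic patch lysines, the acidic C-terminal stretch, the anchor residues)
pinned at their conventional positions.  They are test/demo fixtures, not
curated annotations of the real protein.

## Contact statistics

Two residues are in contact in a frame when their Cα distance is ≤ the
cutoff (default 8.0 Å, boundary inclusive) and, if they share a chain,
their local indices differ by at least the minimum sequence separation
(default 5).  Inter-chain pairs bypass the separation filter: the
concatenated-index gap between protomers has no sequence meaning, and
inter-protomer pairs are exactly the ones a dimer analysis must keep.
Both thresholds are parameters of `ContactCriterion`; the separation test
is `|Δ| ≥ 5` (an "at least five residues apart" reading; configurable).

Contact probability pools all frames of all trajectories with equal weight
per frame, so trajectories contribute proportionally to their length.
Contact maps report probabilities in percent over a residue-group product;
pairs excluded by the separation rule are reported as 0%.  The log display
transform is log₁₀(max(p, floor)) with a default floor of 0.01%, so that
never-observed cells remain representable on a log colour bar; the floor is
explicit and configurable rather than baked into the data.

A contact *event* is a maximal run of consecutive in-contact frames within
one trajectory.  Events touching the first or last frame are flagged
censored — their true duration is only partially observed — and are
*included* in lifetime statistics by default: dropping them would bias the
estimator against long-lived contacts, and the flag lets users re-filter.
Durations convert to lifetime units as
`frames × snapshot_interval_steps / 100,000`; the mean and the population
SD (ddof = 0, switchable) are reported.  The identity
Σ event frames = in-contact frames ties the probability and event
machinery together and is asserted in the tests.

Key-pair tables rank pairs between two regions by probability descending,
ties by mean lifetime descending, then by index pair ascending.
Interaction classes come from a residue-class table (hydrophobic:
A V L I M F W P G C Y; positive: K R H; negative: D E; polar: S T N Q;
overridable per topology): one positive + one negative residue is
ELECTROSTATIC, both hydrophobic HYDROPHOBIC, both polar POLAR, anything
else MIXED, unknown names UNKNOWN with a warning.  This classification is
residue-type-based only; no energetic decomposition is attempted.

## Geometry

Superposition is the least-squares Kabsch fit via SVD with the reflection
branch removed (determinant +1 enforced); (near-)collinear fit selections
raise a conditioning error because the in-plane rotation is undetermined.
An independently implemented quaternion-eigenvalue (Horn) method serves as
the oracle in the tests, never as the implementation.  RMSD series fit
each frame on the rigid-core (restrained) regions and report the deviation
over all residues, with the initial structure as the default reference:
fitting on the flexible parts would absorb the very motion being measured.
Both selections are configurable.

Radius of gyration uses uniform bead masses (one Cα site per residue).
Anchor distances are plain Cα–Cα distances between named or explicit
residue pairs; a centroid-based mode is available through the clustering
module's position machinery for users who prefer centre-of-mass distances.
Histograms report proportions per bin (summing to 1) over 50 equal-width
bins spanning the observed range by default, alongside the sample median
and range.

## Mobile-position clustering

Each frame is superposed onto a reference structure using the reference
region's Cα sites; the centroid of each copy of the mobile region (one
copy per chain carrying it) becomes one 3-D observation.  Seeded k-means
(scikit-learn, `n_init=10`) partitions the observations; k defaults to 5.
Fractions are percentages of all observations — both symmetric copies pool
into one stream — and therefore sum to 100% by construction; clusters are
reported in descending-fraction order.  The occupancy report gives each
centroid's minimum distance to a named special residue set and flags
clusters within a threshold (default 12 Å = the 8 Å contact cutoff plus
4 Å of slack, since a domain centroid sits off the domain surface) as
"covering" that site.  Published cluster-fraction sets that exceed 100%
(overlapping membership or per-copy accounting) cannot arise under these
partition semantics and are not reproduced.

## Synthetic generator

The generator builds the minimal architecture that exercises every
analysis stage: a rigid reference rod of B beads (default 40) at 3.8 Å
spacing on a circular arc (curvature radius 40 Å) standing in for a
BAR-like crescent; rigid compact bodies (4-beads-per-turn helix, 1.2 Å
rise — every non-bonded internal distance ≥ 4.8 Å) on freely-jointed
linkers; and bare flexible tails.  Hard spheres of radius 2.0 Å exclude
volume (bonded neighbours exempt; radius 0 disables exclusion for ideal-
chain work).  Square-well sticky pairs contribute −ε (kT) below their
width (default 8 Å, matching the contact cutoff so well occupancy and
contact probability coincide); optional screened-Coulomb terms contribute
`strength · qᵢqⱼ · exp(−r/λ)/r`.

Sampling is Metropolis Monte Carlo at unit kT with symmetric,
bond-length-preserving moves: crankshaft rotation of a single interior
flexible bead about the axis through its bonded neighbours; pivot of the
entire downstream chain segment (rigid body included) about a flexible
bead or the rod anchor; the pivot about the last linker bead doubles as
the rigid-body orientation move.  Because every move preserves bond
lengths exactly, the harmonic bond term is identically zero under this
move set and the ε = 0, radius-0 limit *is* the freely jointed chain —
which the tests exploit: the tethered 20-bond chain's end-to-end
distribution is compared against direct FJC sampling with a two-sample KS
threshold of 0.05, fixed in advance at ≈1.6× the null 95% quantile for
the sample sizes used to absorb residual autocorrelation.  A separate
two-bead toy (free bead in a hard shell with a square well) checks the
Boltzmann closed form exp(ε)V_in/(exp(ε)V_in + V_out) via batch-means
error bars.

"Time" is counted in attempted moves; recorded-frame lifetimes from the
generator validate the lifetime *estimator* and make no claim about
physical kinetics.  One root seed drives everything: per-trajectory,
calibration and toy streams derive deterministically from it via seed
sequences, and identical seeds give bit-identical trajectories.
Calibration runs use a disjoint seed stream and (default) twice the
production length; a helper checks that calibrated propensities are
monotone non-decreasing across a well-depth grid and warns beyond ~3
combined binomial standard errors.

## Pipeline and provenance

`RunConfig` (YAML) names the inputs or a synthetic preset, toggles stages,
and fixes seeds.  Outputs are TSV with a leading comment naming the
package version and a 12-hex-digit SHA-256 hash of the analysis parameters
(the output directory is excluded from the hash); `provenance.json` echoes
the config, seeds, counts and per-stage timings.  Reruns with the same
config and seed are byte-identical; floats are written at %.10g.

## Problem sizes and numerical choices

Shipped presets use 40–80 beads, 50,000–200,000 MC moves, frames every
100 moves and 2,000–5,000 equilibration moves — sizes chosen so a full
validation cycle (including the independent calibration runs) completes in
a few minutes on one core while leaving binomial errors of ~1 percentage
point on planted propensities.  Statistical assertions in the test suite
use 3–4 standard-error tolerances computed from the actual sample sizes;
exact assertions (unit conversion, oracle equivalence, determinism) use
equality or 10⁻⁹ Å.

## Limitations

* Contacts are Cα-only; side-chain interaction sites are not modelled, so
  the 8 Å criterion is a backbone-proximity proxy.
* The generator makes no attempt to reproduce any real force field's
  energetics, kinetics, or absolute lifetimes; it provides known ground
  truth for estimator validation, not a model of a specific protein.
* Lifetime statistics include censored events; for ensembles with many
  short trajectories the mean is accordingly conservative.
* k-means with Euclidean metric assumes roughly isotropic position
  clusters; strongly curved occupancy shells would need a different
  clusterer (the algorithm and k are configurable and recorded in
  provenance).
* No binary trajectory formats (DCD/XTC); conversion to multi-model PDB or
  the TSV format is assumed upstream.
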