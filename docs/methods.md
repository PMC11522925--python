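# Methods

## Scope and data model

The package post-processes enzyme–polymer trajectories for serine
hydrolases acting on poly(ethylene terephthalate)-like substrates.  A
`MolecularSystem` carries the topology plus the annotations every stage
needs: the catalytic serine's γ-oxygen, the two oxyanion-hole amide
hydrogens, the polymer repeat units, and the ester-bond atom triplets
(carbonyl C, carbonyl O, ester O).  Ester triplets are matched by a
configurable atom-name template per polymer residue because PET
parameterizations do not share a naming convention.  A `Trajectory` is a
frames × atoms × 3 array in Å with optional orthorhombic box, per-frame
time (ns, strictly increasing), and optional replica index and
statistical weight — the carrier for pooled replica-exchange ensembles.

Units: coordinates Å, energies kcal/mol, free energies converted to
kJ/mol (× 4.184; k_B = 0.0083145 kJ mol⁻¹ K⁻¹) only at the
free-energy-surface stage.  Residue numbering is taken verbatim from the
PDB residue field (author 1-based numbering, no renumbering).  Periodic
systems use the orthorhombic minimum-image convention; free space
otherwise.

On-disk formats: PDB for topologies and multi-model trajectories
(Biopython parser), a plain-text frame table
(`#frame time atom x y z [box] [replica] [weight]`, 4-decimal
coordinates) for trajectories, TSV for nonbonded parameters
(atom_name, residue_name, charge, σ, ε).

## Analysis parameters (AnalysisConfig)

| parameter | default | meaning |
|---|---|---|
| contact_cutoff | 3.0 Å | residue–polymer heavy-atom contact distance, boundary inclusive |
| persistence_fraction | 0.75 | minimum weighted fraction of frames for a persistent contact |
| proximal_radius | 12.0 Å | contacting-polymer-to-serine-Oγ split between proximal and distal sites |
| productive_cutoff | 4.0 Å | SER–C and oxyanion distances of a productive pose; inner phase boundary |
| outer_boundary | 6.0 Å | outer phase boundary of the entry coordinate |
| pca_radius | 10.0 Å | ester-C→Cα feature radius for pathway PCA |
| binding_energy_threshold | −10 kcal/mol | binding-onset energy level |
| temperature | 303 K | FES and comparison-threshold temperature |
| coulomb_constant | 332.0636 kcal·Å·mol⁻¹·e⁻² | electrostatic prefactor |
| nonbonded_cutoff | 12.0 Å | pair-energy truncation |

All distance criteria are boundary-inclusive (≤), applied uniformly.
"Heavy atom" means element ≠ H — the field convention for contact
analysis.

## Contacts

A residue contacts the polymer in a frame when the minimum heavy-atom
distance to any polymer atom is ≤ 3 Å.  Contact fractions are weighted
frame means, so duplicating a frame and doubling its weight are
equivalent.  A residue's contact frame is *proximal* when the polymer
atoms in contact with it come within 12 Å of the serine Oγ in that frame;
a residue is labelled proximal (distal) when ≥ 90 % of its weighted
contact frames are, otherwise *both*.  The 90 % majority is a tunable
default — the underlying classification is visual in origin and any
aggregation into one label per residue needs a quantization.  Persistence
is computed per trajectory by default (pooling is a caller choice):
whether it should pool across simulations is genuinely open, and
per-trajectory is the conservative reading.

## Interaction energies

The pair energy between disjoint atom groups is truncated Coulomb plus
Lennard-Jones 12-6 with Lorentz–Berthelot combination, dielectric 1, no
switching function and no long-range correction, cutoff 12 Å.  Absolute
values from this model are not comparable to any particular MD engine's
(PME, switching, exclusions); the pipeline only consumes orderings and
differences — class profiles, onset times, parent-vs-variant shifts —
which are robust to the truncation scheme.  The class profile divides the
sum of per-residue weighted-mean energies in each physicochemical class
by the number of contacting residues of that class.  Class membership:
apolar {A,V,L,I,M,G,P,C}, polar {S,T,N,Q}, charged {D,E,K,R,H}, aromatic
{F,Y,W}; histidine sits in *charged* by default and is overridable,
since class boundaries for H are convention, not physics.  Unit–unit
polymer energies are defined only for non-adjacent units (|i−j| ≥ 2);
adjacent units share an ester bond and their nonbonded energy would be
dominated by through-bond neighbors.

## Entry analysis

The reaction coordinate is the SER–C distance: serine Oγ to the carbonyl
carbon of the nearest ester (nearest chosen per frame).  A frame is a
*productive pose* when SER–C ≤ 4 Å **and** both distances from that
ester's carbonyl oxygen to the two oxyanion-hole hydrogens are ≤ 4 Å — a
conjunction, since both amide hydrogens stabilize the oxyanion.

The *si*/*re* face of the serine's approach is the sign of
n · (Oγ − C) with n = (O − C) × (O_ester − C); |n·(Oγ−C)| ≤ 0.1 Å is
*undefined* (in-plane dead band), and a collinear triplet degenerates to
*undefined* with a warning.  The sign→label assignment is anchored by the
shipped reference geometry `data/reference_ester.pdb`, whose pose is
*si*; a full CIP prochirality engine is out of scope and the anchor makes
the convention testable (mirror reflection must flip every label).

Segmentation emits an event for each passage of the coordinate from
above 6 Å to below 4 Å: the entry phase spans the frames strictly between
the last frame > 6 Å and the first frame < 4 Å; the inside phase lasts
until the coordinate exceeds 6 Å again.  One frame below 4 Å suffices to
close an event — no debouncing by default (a width-5 median filter is
available by flag), because any hysteresis rule would be an invention.
An event is productive when any inside-phase frame holds a productive
pose; its face label is taken at the first productive frame (first inside
frame for nonproductive events).

## Free-energy surfaces

ΔG(bin) = −k_B T ln(P/P_max) over a weighted 2D histogram; default
50 × 50 bins over the sampled range expanded by 5 % (the resolution of
the surfaces this emulates is unstated, and 50² keeps single-trajectory
surfaces well populated).  Unsampled bins are masked, never padded with
pseudo-counts, and are impassable (+∞) for path-finding.  Replica pooling
multiplies frame weights by per-replica weights supplied as data —
the correct down-weighting of higher replicas in a Hamiltonian
replica-exchange ladder depends on the ladder itself, so the scheme is an
input, not a built-in guess (uniform by default).

Features: local minima are sampled bins not exceeded by any sampled
8-neighbor, with equal-valued plateaus collapsed to their lowest (i, j)
index; minima split at the productive boundary (4 Å) on the distance
axis.  The barrier between the deepest productive and nonproductive
minima is the bottleneck (minimax ΔG) over 8-connected paths through
sampled bins, computed exactly by Dijkstra on the bottleneck objective.
Parent-vs-variant comparison flags `stabilized-productive`,
`reduced-nonproductive` and `smoother-path` when the corresponding
feature shifts by more than 1 k_BT (≈ 2.52 kJ/mol at 303 K) — the
smallest physically defensible quantization of a visual comparison.

## Pathway PCA

Features are distances from the tracked ester carbon to every enzyme Cα
that ever comes within 10 Å during entry + inside frames; values are
capped at 2 × radius when a selected residue drifts out of range (PCA
needs complete rows; the cap bounds the leverage of excursions and is
recorded in output metadata).  The fit is an eigendecomposition of the
weighted covariance of column-centered features, components sorted by
eigenvalue with the largest-magnitude loading entry forced positive
(deterministic sign).  Entries are assigned to pathways by k-means
(k = 3, 50 restarts, fixed seed) on per-event mean projections — whole
entries, not frames, are what pathway labels describe — and labels are
ordered by cluster mean PC1 so pathway 1 is the most negative.  The
significance threshold for per-residue contributions defaults to the
uniform-loading baseline 1/√d; the criterion behind published
"significant position" counts is unstated, so the threshold is exposed
as a parameter.

## Kinetics

Both saturation modes fit v = V_max·x/(K_m + x) by bounded nonlinear
least squares (scipy `curve_fit`, tolerances 1e−12), initialized at
V_max = max rate and K_m = x at half-max (interpolated); standard errors
come from the linearized covariance at the optimum.  The conventional
mode varies substrate load (g/L) at fixed enzyme; the inverse mode varies
enzyme (μM) at fixed substrate load — the natural design for an insoluble
substrate whose surface the enzyme saturates.  Secondary parameters:
molar K_m = conventional K_m × a user-supplied g/L→μM attack-site
conversion factor (it depends on the substrate preparation — crystallinity,
surface area — and is deliberately never defaulted); k_cat is either
supplied directly or derived from the inverse-mode plateau divided by the
fixed substrate load, and the source is recorded because both derivations
are in circulation; molar η = k_cat / molar K_m exactly.  Report tables
round half-even to 3 decimals.

## Synthetic study conditions

The generators plant ground truth rather than integrate dynamics —
analytically known truth is the point, so positional noise is Gaussian,
not Langevin:

- **Toy system**: a Cα shell of radius 15 Å (default 40 residues, names
  cycling through all 20 amino acids) around a serine site at the cleft
  mouth, two oxyanion H beads positioned so the final bound pose is
  productive by construction; a straight 5-unit polymer bead chain with
  4 ester triplets (one per junction; the terminal unit carries acid-like
  atom names and no triplet).
- **Entry trajectories** (120 frames, 0.3 Å noise default): the polymer
  translates rigidly along one of three corridor guide curves approaching
  the serine from distinct directions (lateral ±y swings and head-on),
  from ≥ 9 Å down to 3 Å.  The schedule dwells outside, crosses the
  6→4 Å zone quickly (≈ 0.5 Å/frame) and settles inside — mirroring the
  long-adsorbed/fast-entry phenomenology and keeping the noisy crossing
  within ~1 frame of the noiseless one.  Ground-truth boundaries come
  from the noiseless profile's crossings.
- **Contact fixtures**: residue beads toggled between shell and
  2.5 Å-contact positions in an exact number of frames, so planted
  contact fractions are exact; proximal vs distal contacts touch the
  first (near-serine) or last (remote) repeat unit.
- **Boltzmann samples**: Metropolis random walk (step 0.8 Å, thinning 5,
  burn-in 500) targeting exp(−U/k_BT) for analytic potentials
  (harmonic ½k r²; double well a((x/x₀)²−1)² + b y², defaults a = 5,
  b = 2, x₀ = 1.5 — wells ≈ 2 k_BT deep at 303 K, crossable yet clearly
  bimodal); effective sample size from the autocorrelation time.
- **Kinetic data**: x log-spaced over K_m/10…10 K_m (n = 8 default),
  Gaussian noise σ = 5 % of V_max, clipped at zero rate.

What the generators do *not* emulate: conformational flexibility of the
polymer chain (rigid translation only), enzyme internal motion, realistic
force-field energetics, exchange dynamics between replicas, and
measurement error structure beyond i.i.d. Gaussian noise.  Passing tests
therefore demonstrate that the *analysis chain* recovers planted truth
under realistic noise magnitudes — not that any particular enzyme behaves
as the toy does.

## Numerical choices and degenerate inputs

- Distance boundaries inclusive everywhere; ties at a bin edge follow
  numpy histogram semantics (right-inclusive last bin).
- Zero inter-atomic distance in the energy kernel raises (clash) rather
  than returning ±∞.
- A flat FES makes every sampled bin a non-strict minimum; plateaus
  collapse to the lowest bin index with depth 0.
- PCA on a zero-variance matrix, k-means with fewer events than
  clusters, kinetic fits with all-equal rates, and all-zero sample
  weights raise informative errors instead of degrading silently.
- All generators are pure functions of (parameters, seed); reruns are
  byte-identical.

## Known limitations

- The energy model reproduces no engine-specific absolute energies; only
  differences and orderings are meaningful.
- The si/re convention is anchored, not derived from CIP priority rules;
  exotic ester substituents could invert the chemical reading.
- Entry segmentation has no hysteresis by default; trajectories that
  oscillate exactly at a boundary produce short events unless the median
  filter is enabled.
- Headline counts from microsecond-scale published simulations
  (tens of productive entries per enzyme, tens of significant PC1
  positions) require those trajectories and are outside what the
  synthetic conditions can or should reproduce; the property-based suite
  covers the algorithms instead.
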