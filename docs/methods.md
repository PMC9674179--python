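# Methods

`cglandscape` reconstructs, on a fully synthetic stand-in system, the
computational chain used to ask how a bivalent protein clamp (a SUMO-like
partner binding two surfaces of a tandem-RRM RNA-binding domain at once)
restricts the receptor's open/closed hinge motion and thereby amplifies
its RNA-binding affinity. This note records the models, the parameters
that matter, and the choices made where the design was genuinely open.

## 1. Structural similarity (mutual Q)

For two conformations A, B sharing a topology,

    Q = (1/N) * sum_ij exp( -(r_ij^A - r_ij^B)^2 / (2 delta_ij^2) )

over a pair set; `delta_ij = |i - j|^0.15` (in Angstrom) for
intra-molecular pairs and `delta_ij^2 = 5 A^2` for inter-molecular pairs.
A pair enters the set when the sites are within the contact threshold
(12 A) in **either** structure (union rule; the convention is stated in
the literature only for the template comparison, and we apply it
uniformly). Intra-molecular pairs with sequence separation < 3 are
excluded as trivially constrained by chain connectivity (configurable).
Q against a canonical peptide/partner template (`Q_c`) is evaluated over
the interface named by an explicit site mapping; screening keeps models
with `Q_c > 0.2`, strict inequality.

Clustering runs average-linkage hierarchical clustering on the distance
`1 - Q`; cluster representatives maximize mean within-cluster Q (ties to
the lowest frame index). The cluster count defaults to 3 and is a knob.

## 2. Order parameters

**PC0.** Cartesian PCA is performed after iterative least-squares
superposition of every frame onto the evolving mean structure, so the
leading component captures internal (hinge) motion rather than rigid-body
drift. Components are orthonormal rows over flattened coordinates;
explained variances are non-increasing. The sign of PC0 is anchored so
the *open* reference conformer projects positive. On the synthetic
two-state ensemble the hinge mode carries >95% of the variance and the
open/closed conformers project to roughly +/-10 on the PC0 axis; basin
rectangles default to symmetric intervals around those projections (the
published system's printed mode ranges, closed [-10, 0] and open
[10, 30], rescale onto this axis).

**R.** The separation between the geometric center of the pocket-lining
residues and the geometric center of the ligand sites, in Angstrom
(centers unweighted; the source defines R only verbally). Figures quoted
in nm elsewhere convert at the presentation layer only.

**Pathways.** A dissociation trajectory is `path_I` when PC0 enters the
open range before R completes its crossing of the unbound threshold,
`path_II` when unbinding completes with PC0 never leaving the closed
range, `mixed` otherwise. A trajectory that never unbinds is an error,
not a label.

## 3. The synthetic world

Everything is generated by `cglandscape.synthetic`; nothing is
downloaded. The receptor is two compact 40-residue domains built on a
3x3xN lattice (3.8 A spacing, snake-ordered so consecutive residues are
bonded neighbors), joined by a 4-residue linker arched away from the
cleft. The closed conformer places the domains' inner faces 10 A apart;
a 5-nucleotide single-site RNA (the modelled target is a 5-nt RNA) lies
in the cleft. The open conformer is a rigid rotation of domain 2 about
its linker-attachment corner (default 50 degrees) — a book-opening
motion chosen so the domains separate monotonically without steric
collision. Pocket-lining faces carry residue types (R/K/N on one face,
S/T/Q on the other) disjoint from the scaffold alphabet, so a
type-pooled residue-base potential binds the ligand only at the cleft.

The clamp (chain S) is an 18-residue triangular-prism fold laid along
one outer face — three snake rows, so every clamp site carries several
native contacts and the clamp behaves as a folded domain rather than a
floppy strand. Its head (`beta2`) faces the domain-1 `sim` patch, its
turn region (`znf_contact`) the domain-2 `znf_patch`; both receptor
patches span two lattice heights of the y = 0 face. This matters
mechanically: a clamp whose anchor points are collinear, or a clamp that
can bend internally, leaves the receptor free to pivot or splay with
every tether restraint satisfied, and the bivalent constraint transmits
no orientation (we measured exactly this with straight-strand and
planar-hairpin designs before settling on the prism).

Planted "atomic" contacts are realized as pseudo heavy atoms placed
3.1-3.5 A from the target base, in the plane normal to the RNA chain
axis so neighboring bases stay >= one base spacing away; placement keeps
>= 0.4 A margin to the 4.5 A counting cutoff, so a 0.01 A jitter cannot
change a count. The generator verifies the realized counts against the
request and refuses infeasible plantings.

The umbrella-sampling oracle draws exact Boltzmann samples of
`U(x) = k_true x^2 / 2` plus each window's harmonic bias (a Gaussian per
window), so the WHAM estimator is testable against a closed form with no
dynamics involved.

What a green test does **not** establish: the lattice receptor has no
secondary structure, no side-chain packing, a single-site RNA, and an
enthalpy-dominated binding mode; agreements with published magnitudes
are calibrations (Sections 5-6), not predictions.

## 4. Contact energetics

* **Atomic contact counts**: pairs of atoms (pseudo heavy atoms + site)
  within 4.5 A across the protein/RNA interface; at pure CG resolution
  the cutoff defaults to 8 A. Counts pool by (residue type, base type).
* **Residue-base potential**: `eps(type pair) = lambda * pooled count /
  max pooled count`, so eps lies in (0, lambda]. The functional form
  mapping counts to strengths is this package's declared choice (linear
  in pooled counts); type pooling is what lets one table score new
  sequences in the scan stage.
* **Pair energy**: signed well depth times a cosine-tapered switching
  function — full depth inside 6.5 A, tapering to zero over a further
  2 A (C1-continuous, finite-ranged, differentiable for the simulator).
* **Frustration**: for each inter-domain / inter-molecular contact,
  decoys redraw the two identities from the structure's own composition
  (mutational scheme, 1000 decoys default); `z = (mean_decoy - native)
  / SD(decoy)`, minimally frustrated iff `z > 0.78` (the standard
  frustratometer threshold). A homogeneous composition has zero decoy
  variance and is rejected rather than scored.
* **Model ranking**: maximize the minimally-frustrated count, ties to
  the lowest energy.
* **Peptide scan**: windows of the query sequence are threaded onto the
  template peptide sites and scored with a hydrophobicity-product
  potential (positive Kyte-Doolittle part, normalized); the planted
  all-ILE window is the provable global minimum on a polar background.

## 5. Simulator

A structure-based model: harmonic bonds (k = 20 kcal/mol/A^2) along each
chain; Gaussian native-contact wells (depth 2.5 kcal/mol, width 1 A)
for intra-chain pairs within 6.5 A of the reference (inter-domain depth
defaults to 0, leaving the hinge free); residue-base switching wells
scaled by lambda; a soft repulsive wall below 4 A for every remaining
pair (native pairs are excluded from the wall since their reference
distance may sit inside it). The 2.5 kcal/mol depth makes the lattice
domains behave as compact folded units: at shallower wells the domains
breathe so much that PC0 fluctuates by several units with the hinge
locked, drowning the open/closed separation. Dynamics is BAOAB
Langevin, mass 1, dt 0.02 and friction 0.25 in reduced units
(equilibrium bond statistics agree with kT/k within 2% at these
settings; chosen for configurational diffusion speed on one CPU),
kB = 0.0019872 kcal/mol/K, T = 300 K. Every stochastic call takes an
explicit seed; umbrella series derive per-window seeds from a master
seed and are bit-reproducible.

Bias potentials: `harmonic_R` (umbrella on R), `harmonic_PC0`
(alignment-free linear restraint along a fitted PC direction),
`sheet_pairs` (register restraints guiding the SIM/beta2 sheet), and
`crosslink_tether` — harmonic restraints pinning the clamp to both of
its receptor anchor surfaces at their bound-reference distances. The
tether carries zero energy in the closed bound pose and penalizes
opening; it is the bivalent constraint. The guiding protocol is two
phases: biased assembly, then unbiased relaxation.

Umbrella series run windows sequentially, each starting from the
previous window's final configuration, discarding the first 20% of each
window visit; by default the series sweeps outward and then back inward,
pooling both passes per center (bidirectional sampling halves the
seed-to-seed spread of the binding free energy, which is dominated by
hinge-opening hysteresis in the pulled direction). Neighbor-window
histogram overlap is checked and gaps warned.

## 6. Free energies and calibration

WHAM is the standard binned self-consistency iteration (relative
tolerance 1e-7 on window free energies, max 1e5 iterations), surfaces
min-normalized with unsampled bins NaN (never interpolated), and
uncertainties from 50 block-bootstrap replicates (contiguous blocks to
respect autocorrelation; bootstrap replicates warm-start from the
converged window free energies). The 2D surface reweights every sample
with the 1D window free energies (the bias acts on R alone).

`dG_bind` = mean F over the unbound plateau (default: last 20% of the
sampled R range) minus the bound minimum; no standard-state volume
correction is applied (declared: the published 8 kcal/mol is likewise a
profile difference). Errors propagate by recomputing dG on each
bootstrap replicate surface; ddG errors combine in quadrature.

Shoulder detection fits a smoothing spline whose smoothing scales with
the bin *uncertainty* (not the signal variance, which would flatten real
shelves) and reports local minima of dF/dR that dip toward zero without
a sign change; a sign change is a barrier, not a shoulder.

**Calibration.** `calibrate_scale` bisects the global scale lambda (in
log space, monotonicity checked on the bracket) until the umbrella/WHAM
affinity hits the 8 kcal/mol target within 0.5 kcal/mol, mirroring the
published calibration of the residue-nucleic-acid potential strength.
On the demonstration system the loop settles at lambda ~1.41. The
tether spring is calibrated the same way against the published
2 kcal/mol affinity difference; the packaged
`data/demo_calibration.json` stores both. Statistical context measured
at the demonstration sampling (14 windows x 2e5 steps): seed-to-seed
spread of a single dG estimate is ~0.4-0.5 kcal/mol, which is why the
independent-seed ddG re-measurement uses 3e5 steps/window and why ddG
comparisons quote the bootstrap quadrature error.

## 7. Thermodynamic endgame

`dG = -RT ln(Kd / 1 M)` with R = 0.0019872 kcal/mol/K. T defaults to
300 K: at that temperature the measured Kd error-bar endpoints (9.2 and
22.4 uM) reproduce the printed 6.4-6.9 kcal/mol range after rounding,
and `exp(2 / RT) ~ 29` matches the quoted "around 30" equilibrium-shift
ratio. The shift ratio exposes an optional abundance factor defaulting
to 1 (equal-abundance assumption).

## 8. Known limitations

* The receptor is a lattice toy: no secondary structure, no sequence
  realism beyond the type-disjoint faces, single-site RNA. Published
  force-field surfaces are not reproducible here and are covered by
  sign/property checks instead.
* `harmonic_PC0` is alignment-free (projection against a fixed frame),
  so it is meaningful only for well-superposed simulations.
* dG estimates at the demonstration sampling carry ~0.5 kcal/mol
  seed-to-seed spread; block bootstrap mildly underestimates it since
  window-level stitching noise is shared across bins.
* The 1D profile over R has no Jacobian/standard-state correction; the
  unbound "plateau" inherits a weak -2kT ln R slope, absorbed into the
  plateau-averaging convention.
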