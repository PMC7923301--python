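# Methods

## Scope and model

`oligovar` estimates how a dominant missense substitution redistributes
stability and affinity across the mixed WT/mutant assemblies of a
homo-oligomer. The core quantity is a single-structure (one-trajectory)
MM/GBSA apparent ΔΔG: mutant and WT assemblies are scored on fixed
coordinates, separated binding partners keep the complex geometry, and the
unfolded reference of a chain is an extended Gly-X-Gly tripeptide at the
scanned position (φ = ψ = 180°), so every residue except the scanned one
cancels in the WT-vs-mutant difference. No conformational ensembles,
entropy terms, or pKa shifts are modeled. The outputs are comparative
indexes: signs, orderings and groupwise trends are meaningful; absolute
magnitudes are force-field-dependent and are not claimed to match any
particular published or experimental value.

## Energy function

A compact polar-hydrogen fixed-charge force field written for this package
(`forcefield.py`):

- **Charges.** Apolar hydrogens are implicit; polar hydrogens explicit.
  Backbone N/H/CA/C/O carry −0.40/+0.25/+0.10/+0.55/−0.50 e; side-chain
  charges sum exactly to the residue's formal charge at pH 7.5 (Asp/Glu −1,
  Lys/Arg +1, His neutral tautomers). The set is auditable at a glance;
  it is not a fit to quantum data.
- **Lennard-Jones.** Element-based rmin/2 and ε (C 1.908 Å/0.086, N
  1.824/0.17, O 1.661/0.21, S 2.0/0.25, H 0.6/0.0157 kcal/mol),
  Lorentz–Berthelot combination, 1-2/1-3 exclusions, 1-4 scaled by 0.5
  (both LJ and Coulomb).
- **Bonded terms.** Harmonic bonds (k = 300 kcal/mol/Ų, ideal lengths from
  standard peptide geometry) and harmonic angles (k = 60 kcal/mol/rad²,
  109.47° sp³ / 120° sp² by a name-based hybridization table). Proper
  torsions and impropers are omitted: all scanning is done under a
  displacement cap (below), which bounds the conformational drift those
  terms would otherwise restrain.
- **Polar solvation.** Generalized Born with Hawkins–Cramer–Truhlar
  pairwise-descreening effective radii (mbondi-style intrinsic radii,
  0.09 Å offset, element-wise scale factors) and the Still energy
  expression, solute dielectric 1, solvent 80.
- **Nonpolar solvation.** γ·SASA with γ = 0.0054 kcal/mol/Ų; SASA by
  Shrake–Rupley (`biotite.structure.sasa`, 300 sphere points — deterministic
  but orientation-dependent at the few-percent level, which is why
  rigid-motion checks compare rankings, not raw scores, at tight tolerance).
- **Units.** kcal/mol and Å throughout; Coulomb constant
  332.0637 kcal·Å/(mol·e²); kT at 298 K = 0.59219 kcal/mol.

Minimization acts on the MM terms only (bonds, angles, LJ, Coulomb) with
analytic gradients (verified against central differences to 2e-8 relative)
under L-BFGS-B; GB and SASA are evaluated on the resulting structures.

## Preparation

The preparation pipeline mirrors restrained crystal-structure refinement:

- **Water pruning (3.5 Å rule).** A water is deleted iff no non-water heavy
  atom lies within 3.5 Å of its oxygen; decisions are made on the original
  structure and applied simultaneously, so mutually supporting water
  chains are removed as a block. Order-independent.
- **Protonation at pH 7.5, by rule.** Asp/Glu deprotonated, Lys/Arg
  protonated, Cys thiol unless Sγ–Sγ < 2.5 Å (disulfide). The His tautomer
  maximizes the hydrogen-bond count within 3.5 Å: a protonated nitrogen
  donating to a nearby acceptor counts +1, an unprotonated nitrogen
  accepting from a nearby donor counts +1, and ties go to the common
  Nε2-H (epsilon) tautomer. A carbonyl oxygen near Nδ1 therefore selects
  the Nδ1-H tautomer — the donor orientation is the hydrogen-bond-forming
  one. Empirical pKa prediction is out of scope; a config hook accepts
  externally supplied per-residue states.
- **Capped minimization.** "Minimize until the heavy-atom RMSD reaches
  0.3 Å" is read as a displacement *cap*: minimization runs in short
  L-BFGS chunks and keeps the last iterate whose heavy-atom RMSD from the
  input is within the cap. The alternative reading (keep minimizing until
  at least 0.3 Å of motion) would reward drifting away from the
  experimental structure and is rejected. A cap of 0 returns the input
  unchanged; energy is non-increasing by construction.

## Composition scan

`enumerate_compositions(n)` yields all 2ⁿ WT/mutant assignments in
deterministic lexicographic order (2ⁿ − 1 when the all-WT reference is
excluded): 7 trimer and 63 hexamer states. Trimer binding is evaluated
protomer-vs-rest (3 pairings per state, 21 total; groups of 9/9/3 by
mutation count), hexamer binding trimer-vs-trimer (groups equal to
binomial(6,k): 6/15/20/15/6/1). Pooled statistics are the mean and *sample*
SD (n−1 denominator); a single-member group reports no SD (absent, not
zero). `symmetry_reduce` offers orbit representatives under a permutation
group as an opt-in accelerator; by default every composition is evaluated
explicitly, and the reduction is cross-checked against full enumeration in
the tests.

Mutagenesis replaces the side chain atom-by-atom from internal-coordinate
templates. The rotamer library is a compact backbone-independent table of
canonical gauche/trans chi combinations with approximate population
frequencies; selection needs only the frequency *ordering*. The most
probable rotamer passing the clash filter wins (clash: heavy-atom pair
closer than 0.7× the sum of vdW radii; candidates are checked against the
original structure with all flagged side chains removed, so
symmetry-equivalent compositions select symmetry-equivalent rotamers); if
none passes, the lowest-clash rotamer is used with a warning. Ties break
deterministically by probability, clash score, then chi-angle order.
Buildable targets are the 17 residue types with templates (Trp and Pro are
parameterized for energies but not buildable as mutation targets).

Every composition — the all-WT reference included — then receives the
identical local relaxation: side chains within 4 Å of the scanned site in
*all* protomers are MM-minimized under the same 0.3 Å displacement cap used
in preparation. The cap matters twice: it applies the same refinement
convention as the reference structure, and it prevents individual
compositions from wandering into unrelated local minima, which would add
composition-dependent noise of several kcal/mol to the pooled trends. One
relaxed structure per composition is reused across its binding pairings.

## Electrostatics

The linearized Poisson–Boltzmann equation at zero ionic strength is solved
by finite differences: 7-point stencil, harmonic-mean link dielectrics,
trilinear charge spreading, Dirichlet boundary from the Coulomb far field,
conjugate gradients with Jacobi preconditioning (relative tolerance 1e-10,
residual recorded). Parameters follow the standard surface-map convention:
solute dielectric 1, solvent 80, probe 1.4 Å, 298 K, 5 Å grid extension;
default spacing 0.8 Å (0.3 Å for energy-grade solves). The solute cavity is
bounded by the solvent-excluded surface, evaluated as a signed field
`min(distance to the vdW union, probe − distance to the solvent-accessible
exterior)` — exact for convex regions (a lone sphere's SES is its vdW
sphere), reentrant patches closed to grid resolution by a Euclidean
distance transform. Reaction-field energies subtract a uniform-dielectric
solve on the identical grid, cancelling the grid self-energy exactly; the
Born ion (2 Å, +1 e) reproduces the closed form within 0.6% at 0.3 Å
spacing. Surfaces are triangulated by marching cubes; molecular-surface
maps default to the −0.3…+0.3 kT/e color scale (raw values retained,
clamped only at render time) and isopotential shells to ±10 kT/e.

## Surface analysis

Aggregation/association propensity is a transparent patch-based score, in
the spirit of published aggregation-surface indexes but with documented
weights (the proprietary weighting of commercial tools is not reproduced,
so only rankings, never raw score values, are compared). Exposed atoms
(SASA > 0.5 Ų) are classed hydrophobic (C/S with |q| < 0.25 e) or
electrostatic (|q| ≥ 0.25 e); patches are connected components within 5 Å,
minimum 3 atoms. Per-residue score = 1.0 × (SASA of its atoms in
hydrophobic patches) − 0.5 × (charge-weighted SASA in electrostatic
patches). Residues with relative SASA below 5% (Tien-style maximum-SASA
normalization) are flagged buried and excluded from the rank permutation.
Burying a residue in a complex cannot increase its hydrophobic
contribution; for charged residues the subtracted term also shrinks under
burial, so the *combined* score is provably monotone only for apolar
residues — the tests assert exactly that.

## Synthetic fixtures — what they do and do not show

The generator builds ideal α-helical protomers (φ = −57°, ψ = −47°), not
β-sandwich mimics: the pipeline's contracts are topological and chemical,
not fold-level. The C3 trimer places three identical helices at 7.5 Å from
the z axis with a glutamine planted so its side chain faces the axis
(verified post-generation: < 4.5 Å from both neighbors, no inter-protomer
clash) and a glutamate one helix turn below on the same face. That acidic
shoulder is part of the study conditions: it makes the interface carry
negative charge in the WT state, so a single Gln→Glu swap already meets
repulsion — the geometric forcing that makes "ΔΔG positive and
non-decreasing in mutation count" a property of the fixture rather than a
coincidence of one seed. The head-to-head hexamer flips a second trimer
180° about x at 24 Å centroid separation (closest approach ≈ 3.5 Å, a
genuine contact). The trend pair re-uses one protomer sequence with the
planted face rotated toward the axis or toward solvent. A single integer
seed controls all randomness (0.02 Å coordinate jitter, applied before
symmetry replication so trimers stay exactly C3); the same seed yields
byte-identical PDB output.

Passing tests on these fixtures demonstrate that the machinery — state
enumeration, cycle arithmetic, decomposition bookkeeping, trend direction
under a planted interface charge — is correct. They do not demonstrate
force-field accuracy on real proteins, β-sandwich interface packing,
glycans/ligands, or the magnitude of any specific disease variant's effect.

## Numerical choices and degenerate inputs

- Exact-zero contracts: the all-WT composition's ΔΔG values are identically
  0 (the reference is subtracted from itself); zero charges give an
  identically zero PB field.
- Cycle closure and decomposition conservation are arithmetic identities,
  asserted to 1e-9 and 1e-6 kcal/mol respectively.
- Born radii are clamped to at most 1000 Å when descreening would drive
  1/R negative.
- Isopotential levels outside the grid's value range return an empty mesh
  with a warning; superposition with fewer than 3 paired atoms, clashing
  head-to-head templates, non-group permutation sets, and coincident point
  charges raise typed errors.
- Kabsch superposition always returns a proper rotation (reflection
  corrected via the smallest singular vector).
- Pooled SD uses the sample (n−1) convention; absent, not zero, for n = 1.

## Known limitations

Polar-hydrogen charges and two-body GB are crude relative to modern force
fields; absolute ΔΔG magnitudes should be read as indexes only. The PB
solver handles zero-salt linearized problems on a single uniform grid (no
focusing, no nonlinear term). Protonation is rule-based, not continuum- or
ensemble-based. Mutation targets are single sites (no multi-site
simultaneous scanning) and backbone atoms never move during placement.
mmCIF writing, NMR multi-model files, ligands and glycans are out of scope.
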