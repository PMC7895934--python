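# Methods

This note records the models, conventions and defaults behind each analysis,
the design choices made where more than one convention is defensible, and
what the synthetic fixtures do and do not establish about real data.

## Coordinate model and selections

Structures are chain → residue → atom hierarchies keyed by *author* residue
numbering (1-based, inclusive ranges; insertion codes sort after the bare
number), the numbering used in all RAS/RAF literature (e.g. the G-domain
fitting set Y4-N26, Y40-L56, D69-H166 = 138 Cα atoms). Parsing and writing of
PDB (fixed-column v3.3) and mmCIF delegate to gemmi; model 1 of multi-model
files is used unless another index is requested (the NMR comparator has an
identified representative model). Alternate locations are reduced to one atom
per (chain, residue, atom name) by keeping the highest occupancy, ties broken
by lexicographic altloc id — deterministic and the common convention.
Hydrogens and waters are parsed but excluded from analyses unless explicitly
included, since deposited X-ray entries carry no hydrogens. Chain roles
(GTPase vs effector) are discovered from residue numbering — a polymer chain
starting below residue 20 and ending by 200 is the GTPase, one starting at 52
or later is the RAF construct — because deposited entries do not fix chain
ids.

## Superposition and domain motion

Kabsch fitting uses the SVD of the centered cross-covariance with the
standard determinant guard, so reflections are impossible by construction;
degenerate inputs (< 3 atoms, rank < 2) raise rather than return a spurious
fit. The test suite checks the RMSD against an independent quaternion
(Horn) oracle to 1e-9 on random instances.

Domain motion between two structures sharing an anchor: both are superposed
on the anchor selection, and the residual rigid transform x → Rx + t of the
domain is decomposed into rotation angle arccos((tr R − 1)/2) (clamped to
[−1, 1]), axis from the antisymmetric part of R with the 180° case handled by
eigen-decomposition, screw displacement t·axis (the translation component
along the axis, invariant under the choice of rotation centre), and the total
centroid shift. Sources reporting a single "displacement" rarely say which of
these they mean, so both are emitted and either may be compared; for a pure
screw motion they coincide. Atoms are paired across structures by
(chain-role, residue number, insertion code, atom name) after an explicit
chain-role map; unmatched residues are dropped with a logged count, since
deposited entries differ in ordered residues.

## Interface analysis

**SASA.** Shrake-Rupley quadrature with an element radius table (C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, Zn 1.39 Å), probe 1.4 Å, and 960 points per
atom on a deterministic golden-spiral set — no randomness, so areas are
bit-reproducible. The implementation is in-package (the parameters above are
part of the contract) and is verified three ways: the isolated-sphere closed
form 4π(r+p)² to 1e-9 relative, the analytic two-intersecting-spheres cap
formula to 2%, and an independent Shrake-Rupley implementation (biotite) to
2%. Convergence: 960 vs 4000 points differ by < 2% on fixtures. Buried area
per partner is SASA(partner isolated) − SASA(partner in the two-partner
complex), clamped at zero. Published buried-area figures for these complexes
come from an unnamed area program with unknown radii, so cross-program
agreement better than ~10% should not be expected.

**Contacts.** PDBSum/HBPLUS-style criteria. Without explicit hydrogens (the
X-ray case): hydrogen bond = donor/acceptor heavy pair (typing from a
residue-atom dictionary; backbone N donates except proline, backbone O/OXT
accepts) at ≤ 3.5 Å; salt bridge = Asp/Glu carboxylate O or OXT vs Lys NZ,
Arg NE/NH1/NH2 or His ND1/NE2 at ≤ 4.0 Å; non-bonded contact = any other
heavy pair ≤ 3.9 Å. With hydrogens present the H···A ≤ 2.5 Å and
D-H···A ≥ 90° conditions apply additionally. Each atom pair is classified
once, precedence salt bridge > hydrogen bond > non-bonded (a residue pair may
still contribute several contacts through different atom pairs). Hetero
groups (nucleotide analog, Mg²⁺, Zn²⁺) are excluded from partner selections
unless included explicitly: these are protein-protein interface metrics.
Correctness is checked against a brute-force all-pairs double loop with its
own typing tables, and against planted-contact fixtures recovered exactly.

**Zinc sites.** One site per Zn atom with ≥ 3 coordinating residues among
Cys SG, His ND1/NE2 and Asp/Glu carboxylate oxygens within 2.8 Å (generous
around the ~2.3 Å Zn-S bond but short enough to exclude second-shell atoms).

## Membrane pose and occlusion

**Angles.** Tilt = angle between the α5 long axis and the bilayer normal.
The α5 axis is the first principal axis of the Cα atoms of residues 152-166,
oriented N→C; PCA is the standard long-axis estimator where no formula is
prescribed. Rotation is the signed angle, about the α5 axis, from the
projection of the inward membrane normal to the projection of a body-fixed
reference vector (α5 centroid → α4 centroid, residues 127-136, perpendicular
component), plus a constant offset of −15° chosen so the α4/α5-facing family
reads −15°, which also places the α3/α4 and β1-β3 faces near −85° and 105°.
Only these three landmark values constrain the convention; the offset makes
the construction self-consistent, and `construct_pose` is the exact inverse
of `pose_angles` (round trip exact to < 1e-6°, property-tested). At tilt = 0
all rotations are equivalent and 0 is reported by convention. Rotation bins
wrap at ±180°, tilt bins do not; bins are assigned by nearest centre on a
grid anchored at 0° with ±5° half-width by default.

**Occlusion.** N_res_clash counts residues with any atom within 1.0 Å
(0.1 nm) of any lipid atom — the cutoff is fixed by definition, overridable.
d_Gz is the signed projection of (G-domain COM − bilayer COM) on the normal,
positive on the protein side. Where the source convention is unstated we use
the mass-weighted COM over heavy atoms of residues 1-169: mass weighting is
what MD analysis tools default to, and 1-169 is the construct boundary of the
crystallised G-domain. Ensemble averages over equilibrium snapshots use
uniform weights (equilibrium samples are already Boltzmann-distributed); an
explicit per-pose weight input is accepted for reweighted ensembles.

**Alignment.** A whole complex is carried onto a posed reference KRAS by the
Kabsch transform of the Cα fitting set (4-26, 40-56, 69-166, omitting the
flexible N-terminus and switch regions); every atom, including the effector
chains and hetero groups, moves rigidly together.

## Binding isotherms

Steady-state 1:1 Langmuir model R(C) = Rmax·C/(K_D + C), least squares with
deterministic starts (Rmax at 1.1× the largest response; K_D at the
concentration whose response is nearest half of that) and positivity bounds.
Data that cannot determine the parameters — fewer than 4 concentrations,
less than one decade of span, flat or all-zero responses — return a
non-converged flag with no parameters instead of raising. Replicates are
fitted independently and panels report mean ± SD of K_D per variant, the way
SPR mutant panels are reported. Kinetic (on/off-rate) and mass-transport
models are out of scope.

## Synthetic fixtures: what they emulate, and what they do not

- *Planted complexes* are idealised poly-alanine α-helices (rise 1.5 Å,
  twist 100°/residue) 14 Å apart with substituted side-chain pseudo-atoms
  carrying the donor/acceptor or charged chemistry. Planted sites are strided
  three residues apart so every non-planted inter-chain pair is strictly
  outside all cutoffs; planted distances are drawn strictly inside them
  (H-bond 2.75-3.35 Å, salt bridge 3.30-3.90 Å, non-bonded 3.55-3.85 Å).
  They validate contact enumeration and classification exactly, but their
  side-chain geometry is not stereochemically realistic, so they say nothing
  about, e.g., H-bond angular criteria on real side chains.
- *The Cα-only reference body* has its α5 helix (152-166) along +z and α4
  offset in +x, fixing the body frame; the effector stand-in places the two
  CRD loops (143-151, 157-164) protruding beyond the α4/α5 face, reproducing
  the qualitative arrangement in which membrane-proximal α4/α5-facing poses
  insert the CRD loops first. Real side-chain packing, electrostatics and
  lipid specificity are not modelled.
- *Lipid slabs* are two pseudo-atom grids; the clash count and d_Gz depend
  only on atom positions and the bilayer COM/normal, so grids suffice. A 2 Å
  grid bounds the lateral distance to the nearest pseudo-atom by √2 Å, which
  is adequate for the 1 Å clash cutoff at the fixture scale.
- *Pose ensembles* default to tilt ~ N(90°, 10°), rotation ~ N(−15°, 10°)
  (the α4/α5-facing family) and d_Gz = 30 Å ± 0.5 Å, a realistic
  membrane-proximal G-domain height; the generative per-bin d_Gz means are
  carried as truth and recovered by the binned summary within sampling error.
  These ensembles exercise the binning/averaging machinery only — the
  *actual* orientation populations of KRAS on an anionic bilayer came from
  hundreds of microseconds of all-atom MD and are far beyond desk scale, so
  no claim about them is made or tested here.
- *Isotherms* use the affinities measured for the RAF1 constructs (RBD
  356 nM, tandem RBDCRD 152 nM) as generator inputs with 2% Rmax Gaussian
  noise over 8 concentrations (10 nM-20 µM). Synthetic recovery shows the
  fitter is unbiased and precise at this design; it does not validate the
  published values themselves, whose raw titration points are not public.

All generators take explicit seeds, use one named numpy Generator each, and
are bit-reproducible.

## Problem sizes and numerical tolerances

The default verification scales are: 100 random instances for the
Kabsch-vs-quaternion check (agreement to 1e-9 Å), 50 seeded rigid-motion
fixtures (angle and screw recovered to 1e-6), 20 planted complexes for exact
contact recovery, 960-point SASA quadrature (2% vs closed forms), 100-pose
angle round trips (1e-6°), 2000-pose ensembles for bin conservation and d_Gz
recovery, and 200 noisy isotherms for the median-error bound (< 5% at 2%
noise). These sizes keep a full run in seconds on one core while leaving the
statistical checks well-powered.

## Known limitations

- Contact typing covers the 20 standard residues plus backbone; modified
  residues need explicit radius/typing overrides.
- The H-bond criteria are distance-based when hydrogens are absent, as in
  PDBSum; side-chain rotamer ambiguity (His, Asn, Gln flips) is not resolved.
- No symmetry-mate generation: interfaces across crystallographic symmetry
  are invisible unless the assembly is expanded upstream.
- The rotation-angle calibration fixes the α4/α5 family at −15° by
  construction; absolute rotation values for other bodies than KRAS require
  re-deriving the body frame landmarks (α4/α5 residue ranges are
  configurable).
- `buried_sasa` assumes the two partners are the whole system of interest;
  third chains are ignored rather than treated as environment.
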