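# Methods

`oligolens` analyses ensembles of short peptide oligomers — its default
system is the octamer of the hIAPP amyloidogenic core, residues 20–29
(SNNFGAILSS, acetyl/amide capped), with or without simplified melatonin at
a 1:4 peptide:ligand molar ratio — using purely geometric criteria. This
note records the models, conventions and numerical choices, and what the
synthetic ensembles do and do not emulate.

## Units and data model

Internal units are nm for lengths and kcal/mol for energies; PDB I/O
converts Å↔nm at the boundary. The topology carries chemistry the analyses
need: donor (heavy atom, hydrogen) pairs, acceptor heavy atoms, ordered
aromatic rings, and methyl carbons, attached from packaged plain-text
residue templates. Only polar (donor) hydrogens are represented; nonpolar
hydrogens are omitted because every detector operates on heavy atoms and
the hydrogen-bond criterion needs only the donor hydrogen. Cap groups
(CH3CO / NH2) are classified as main-chain: they extend the backbone amide
chain. Ligand atoms sit outside the main-chain/side-chain partition and are
treated as their own interaction class.

Analyses assume pre-imaged (molecule-whole) coordinates; the minimum-image
convention is applied to inter-molecular distances when a frame carries an
orthorhombic box, but molecules are never re-wrapped.

## Interaction criteria

* **Contact**: two non-hydrogen atoms within 0.54 nm.
* **Hydrogen bond**: donor–acceptor distance < 0.35 nm and D–H–A angle
  > 150°. Inter-peptide bonds are classed MC–MC / MC–SC / SC–SC by the
  heavy atoms' backbone/side-chain membership; peptide–ligand bonds are a
  separate class and never count toward the inter-peptide distributions.
* **Stacking**: rings are paired by minimum centroid distance; the
  interplane angle is folded to [0°, 90°]. Classification: parallel ≤ 30°,
  herringbone ≥ 50°, intermediate otherwise (config-overridable; the
  herringbone basin of Phe–melatonin pairs sits near 60°, 0.48 nm).
* **CH–π distance**: methyl-carbon–to–ring-centroid, minimised over the
  annotated methyls (Ile: CG2, CD1; Leu: CD1, CD2). Carbon-to-centroid is
  rotation-stable and reproduces the 0.35–0.36 nm peak regime.

Ligand binding probability is reported per (frame, peptide chain): the
fraction of such units in which any ligand heavy atom contacts the
residue. A per-ligand-copy variant is available (`per_copy=True`).

## Secondary structure (DSSP-lite)

Backbone hydrogen bonds use the Kabsch–Sander electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol, r in Å

with a bond assigned at E < −0.5 and, as in DSSP, only each donor's two
lowest-energy bonds retained. Missing amide hydrogens are reconstructed at
0.10 nm from N along the bisector of the N−C(prev) and N−O(prev)
directions; prolines and uncapped first residues are skipped. The 8-state
code follows the classic rules: n-turns (i → i+n, n = 3,4,5), with two
consecutive turns giving G/H/I; parallel/antiparallel bridge patterns
giving B and ladders (≥2 consecutive bridges) E; bend S where the
Cα(i−2)→Cα(i)→Cα(i+2) direction changes by more than 70°; priority
H > E > B > G > I > T > S > C. PPII and newer extensions are not
implemented. The six reporting categories pool H/G/I as helix, with E
β-sheet, B β-bridge, T turn, S bend, else coil. Error bars on populations
are standard errors over five equal trajectory blocks.

On a panel of generated fixtures (ideal helix, parallel and antiparallel
two-strand sheets, random coils), residue-level agreement with the
reference DSSP implementation in `mdtraj` exceeds 95%; the residual
differences are at chain termini.

## SASA

Shrake–Rupley with a 0.14 nm water probe and Bondi radii (C 0.170, N
0.155, O 0.152, S 0.180 nm); hydrogens excluded. Sphere sampling uses a
deterministic golden-spiral lattice (default 960 points, bit-reproducible;
single-sphere error < 1%). Neighbour search uses a k-d tree. The SASA axis
of the free-energy landscape covers peptide heavy atoms only, so the
octamer's compactness is comparable across systems with and without
ligands.

## Ensemble statistics

* 1D PDFs are normalized density histograms (Freedman–Diaconis binning,
  fallback 50 bins; zero-variance input collapses to a single unit-mass
  bin).
* The 2D PMF is F = −RT ln H over a 50×50 grid padded by half a bin, with
  R = 0.0019872 kcal/(mol·K), T = 310 K by default, the minimum over
  defined bins shifted to zero, and empty bins flagged undefined rather
  than zero-filled.
* Daura (gromos) clustering runs on the full pairwise post-fit Cα-RMSD
  matrix at a 0.45 nm cutoff. Neighbour counts include self; ties break to
  the lowest frame index. The RMSD matrix fixes the chain order — the
  8-fold permutation degeneracy of identical peptides is deliberately not
  minimised over, matching standard gromos-cluster behaviour; the cluster
  census therefore distinguishes permuted but otherwise identical
  arrangements. Every run audits that members lie within the cutoff of
  their medoid.
* RMSD time series use frame 0 of the input as reference, and the Cα set
  of all peptide chains jointly (not per-chain averaged).
* The convergence check compares two frame windows on three observables —
  secondary-structure populations, the end-to-end-distance PDF, the
  inter-peptide main-chain H-bond-count PDF — via Jensen–Shannon
  divergence in bits on a shared binning, converged iff all three are
  below 0.05 bits (config-overridable; window choice is always explicit,
  never guessed). Note the finite-sample JSD bias ~ (bins−1)/(2N ln 2):
  windows need enough samples for the threshold to be meaningful.

## Synthetic ensembles

The generator is a conformer mixture, not a physics simulator: it emulates
the *composition* of the study ensembles (secondary-structure fractions,
oligomer size, ligand stoichiometry and stacking geometry) so that every
pipeline stage is testable at desk scale. It does not emulate
thermodynamics, kinetics, realistic packing of aggregates, solvent, or
force-field energetics — recovery tests therefore validate the analysis
code, not any claim about real ensembles.

* The peptide builder grows the backbone by internal-coordinate extension
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°;
  ω = 180°), attaches side chains at a single fixed rotamer per residue
  (χ1 ≈ −65° where free), and places amide hydrogens by the bisector rule.
* The β-sheet builder translates the extended strand along its mean
  carbonyl direction (initialised at 0.48 nm). The inter-strand rigid step
  (stagger, spacing, lift, small axial rotation) is tuned once per
  sequence/registry by a deterministic grid search plus bounded
  Nelder–Mead refinement, minimising the summed (clipped at −3 kcal/mol)
  Kabsch–Sander energy of near-register pairs under a steric wall at
  0.24 nm heavy-atom separation. This yields interior-residue E
  assignments in both this package's DSSP and the mdtraj reference.
* The simplified melatonin is rigid and idealized: planar indole (benzene
  + pyrrole annotated separately; only the benzene ring participates in
  stacking analyses), 5-methoxy oxygen and amide carbonyl as acceptors,
  indole and amide N–H as donors; 17 heavy atoms.
* Coil conformers sample (φ,ψ) uniformly outside the helix and strand
  basins, with heavy-atom self-clash rejection (< 0.25 nm between residues
  ≥ 2 apart). Each ensemble builds a seed-derived pool (16–192 conformers,
  scaling with ensemble length) and draws chains from it.
* Composition targets are met by calibration: the generator measures the
  secondary-structure cell yield of each conformer state (sheet-pair,
  helix, coil pool) under the ensemble's own coordinate noise, then solves
  for chain-state probabilities whose expected cell fractions match the
  targets (β via the sheet state; coil via the mix; helix absorbs slack).
  Infeasible targets are clamped toward the nearest achievable value.
  Sheet states are assigned to chain pairs, since an isolated strand
  cannot satisfy the ladder definition.
* Units (sheet pairs, single chains) are packed at random orientations in
  a cubic box (edge 3× the largest unit extent) with rejection below
  0.30 nm inter-unit atom separation; ligands are placed either stacked on
  Phe rings at a prescribed (angle, centroid distance) — at most one per
  ring — or randomly at ≥ 2 nm from all peptides. Isotropic Gaussian noise
  (default σ = 0.005 nm, small enough not to flip hydrogen-bond
  assignments) is added last. All randomness flows from the single
  scenario seed; identical specs give bit-identical trajectories.

Default scenario conditions mirror the study systems: 8 peptides, 32
ligands when present (1:4), composition targets (β 0.16, coil 0.52)
without ligand and (β 0.02, coil 0.60) with, stacking placement at
(60°, 0.48 nm).

## Problem sizes

Generated test ensembles use 400 frames for parameter-recovery checks
(binomial sampling error well inside the ±0.03 recovery tolerance), 300
frames per system in the reproduction script, and 6–20 frames for
pipeline plumbing tests. These sizes were chosen so statistical tolerances
are meaningful at desk scale.

## Known limitations

* Single rotamer per side chain; no rotamer libraries, no protonation
  variants (His is the NE2-H tautomer).
* DSSP-lite omits PPII and π-helix edge-case refinements beyond the
  classic rules; terminal-residue bridge conventions can differ from other
  implementations by a residue.
* The PDB reader accepts only orthorhombic boxes; binary trajectory
  formats (XTC/DCD/GRO) are out of scope.
* Generated ensembles are geometric stand-ins: quantities that depend on
  realistic energetics (cluster censuses, binding probabilities of freely
  diffusing ligands) reflect the generator's construction, not physics.
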