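# oligolens

Geometric trajectory analysis for small peptide-oligomer ensembles, built
around the amyloidogenic core of human islet amyloid polypeptide
(hIAPP 20–29, SNNFGAILSS) and its modulation by small aromatic ligands
such as melatonin.

Aggregation of hIAPP into β-sheet-rich oligomers is linked to β-cell loss
in type-2 diabetes, and small molecules that suppress β-sheet formation in
the 20–29 core are candidate aggregation inhibitors. Assessing such an
effect from simulation output requires a consistent analysis stack, which
this package provides as a library plus CLI:

* **Interaction detectors** — atomic contacts (non-hydrogen atoms within
  0.54 nm), hydrogen bonds (d(D,A) < 0.35 nm and ∠D–H–A > 150°),
  inter-peptide residue–residue contact-probability maps, ligand binding
  probabilities and H-bond profiles, π–π stacking (closest-ring centroid
  distance and interplane angle) and CH–π minimum distances.
* **Secondary structure** — a self-contained Kabsch–Sander assignment
  ("DSSP-lite": H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
  1/r_CN) kcal/mol, bond at E < −0.5; turns, bridges, ladders, bends;
  8-state code mapped to helix/β-sheet/β-bridge/turn/bend/coil).
* **SASA** — Shrake–Rupley with a 0.14 nm water probe on a deterministic
  golden-spiral lattice.
* **Ensemble statistics** — observable PDFs, free-energy surfaces
  F(x,y) = −RT ln H(x,y) at 310 K (e.g. over SASA and radius of
  gyration), Daura/gromos conformational clustering at a 0.45 nm Cα-RMSD
  cutoff, and a three-observable Jensen–Shannon convergence check.
* **Synthetic ensembles** — a deterministic conformer-mixture generator
  (peptide builder from φ/ψ, hydrogen-bond-tuned β-sheet oligomers,
  idealized melatonin placed at prescribed stacking geometries, seeded
  composition targets) so the full pipeline is testable without an MD
  engine or deposited trajectories.

Multi-model PDB (MODEL/ENDMDL, optional CRYST1) is the trajectory
interchange format; all outputs are TSV tables with provenance headers.

## Worked example

Generate a melatonin-analog scenario (8 peptides, 32 ligands, low-β
composition, ligands stacked on Phe rings at the herringbone geometry) and
analyse it:

```python
import numpy as np
from oligolens import ScenarioSpec, generate_ensemble, \
    assign_secondary_structure, ss_population
from oligolens.core import select, Trajectory
from oligolens.ensembles import daura_cluster
from oligolens.interactions import stacking_events

spec = ScenarioSpec(
    n_peptides=8, n_ligands=32,
    composition={"beta": 0.02, "coil": 0.60},
    ligand_placement={"mode": "stacked", "angle": 60.0,
                      "distance": 0.48, "fraction": 0.25},
    n_frames=100, seed=1)
traj = generate_ensemble(spec)

for cat, (f, se) in ss_population(assign_secondary_structure(traj)).items():
    print(f"{cat:12s} {100*f:5.1f}% +- {100*se:.1f}")

ca = select(traj.topology, "peptide and name CA")
print("clusters:", daura_cluster(traj, ca, cutoff=0.45).n_clusters)

top = traj.topology
mel = [(ri, 0) for ri, r in enumerate(top.residues) if r.name == "MEL"]
phe = [(ri, 0) for ri, r in enumerate(top.residues) if r.name == "PHE"]
ev = [e for e in stacking_events(
          Trajectory(topology=top, frames=traj.frames[:10]), mel, phe)
      if e.centroid_distance < 0.6]
print("median stacking angle:", round(np.median([e.angle for e in ev]), 1),
      "distance:", round(np.median([e.centroid_distance for e in ev]), 3))
```

Output:

```
helix         19.4% +- 1.1
beta_sheet     1.6% +- 0.4
beta_bridge    0.0% +- 0.0
turn           1.2% +- 0.1
bend          17.3% +- 0.9
coil          60.6% +- 1.2
clusters: 100
median stacking angle: 60.2 distance: 0.48
```

The measured β-sheet (1.6%) and coil (60.6%) fractions recover the
scenario's composition targets within sampling error, and the stacking
detector reads back the prescribed herringbone placement (60°, 0.48 nm).
Every frame is its own cluster here because randomly packed octamer
arrangements are all distinct at the 0.45 nm cutoff — see
`docs/methods.md` for what the generator does and does not emulate.

The same pipeline runs from the shell:

```bash
oligolens generate --out octamer.pdb --seed 1 --frames 100 \
    --peptides 8 --ligands 32 --beta 0.02 --coil 0.60
oligolens pipeline --traj octamer.pdb --out analysis/
```

`analysis/` then holds the full figure-data set: secondary-structure
populations (overall and per residue), RMSD/end-to-end/H-bond-count PDFs,
the SASA–RG free-energy surface with the top-10 cluster projection,
MC–MC and SC–SC contact maps, ligand binding/H-bond profiles, the
stacking PMF and CH–π distance PDFs.

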