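# helixforge

Screw-transform analysis, classification and construction of filamentous
and cyclic protein assemblies, with RecA as the worked system.

Any rigid placement of one protein monomer relative to a copy of itself
defines a screw motion — a rotation `theta` about an axis combined with
a translation `trans` along it — and therefore a unique regular
assembly: a helix, a ring (`trans = 0`), or a straight filament
(`theta = 0`). helixforge extracts these screw parameters from
coordinates, derives the global helix descriptors

```
N = 360 / theta      (monomers per turn)
P = N * trans        (pitch, Å)
dir = R if theta * trans > 0 else L
```

and uses them to characterize, filter, and build assemblies:

* **structures** — PDB I/O (biotite-backed), flexible-region pruning,
  crystal-symmetry neighbor reconstruction, coarse-grained reduction
  (~4 heavy atoms per bead, charges on ionizable side chains).
* **geometry** — Kabsch superposition, screw ↔ transform decomposition
  (exact round trip), helix parameters, angular deviations.
* **assembly** — regular filaments of arbitrary length, mixed-mode
  filaments (with super-helix analysis of the repeat block), curved-axis
  construction on arbitrary guide curves (rotation-minimizing frames),
  two-strand supercoiled filaments.
* **energetics** — reduced force field (smooth 8-6 van der Waals +
  Coulomb screened by a distance-dependent dielectric, energies in RT at
  300 K), per-residue best-energy maps, cross-turn steric screen.
* **docking** — multi-start rigid-body self-docking (global
  quasi-spherical shell at ~10 Å spacing, or targeted 2 Å grid within
  20 Å of a reference), analytic-gradient local minimization, energy
  window / boundary-residue / deduplication filters.
* **classify** — Filament / Cyclic / NearCyclic / NearHelical
  classification of each binding geometry, and Monte-Carlo adjustment of
  near-cyclic poses to exact C_k symmetry.
* **metrics** — residue contacts, f_NAT / f_IR, ligand- and
  interface-RMSD, Shrake-Rupley SASA, buried-surface-area decomposition
  by region truncation, groove-width profiles.
* **mc** — f_NAT-constrained Metropolis exploration of a binding-mode
  family with per-step helix descriptors.
* **fixtures** — deterministic synthetic monomers and assemblies so the
  full pipeline is testable without any downloads.

## CLI

The `hw` command exposes the main operations:

```bash
hw analyze A.pdb B.pdb            # screw + helix parameters of a monomer pair
hw build monomer.pdb --screw 60,14.17 -n 24 -o filament.pdb
hw prune monomer.pdb --regions regions.yaml -o core.pdb
hw reduce monomer.pdb             # coarse-grain summary
hw energy A.pdb B.pdb             # reduced-representation interaction energy
hw dock receptor.pdb ligand.pdb --mode global --seed 1
hw classify --n 5.95 --pitch 0.2 --rm 30
hw metrics refA.pdb refB.pdb testA.pdb testB.pdb
hw groove filament.pdb --screw 58.06,15.16
hw explore receptor.pdb ligand.pdb --steps 1000 --seed 7
hw fixture --shape horseshoe --residues 36 --screw 60,0 -n 6 -o ring.pdb
```

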