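# rigidkit

Combinatorial rigidity analysis of graphs and molecular structures.

Given a graph, which parts of it are *rigid* — forced to move as a single
block — and which parts are flexible? For bar-and-joint or body-and-bar
frameworks in the plane and in space, generic rigidity is a purely
combinatorial property captured by (k,ℓ)-sparsity counts, and the
**pebble game** decides it in polynomial time while also extracting the
vertex-maximal rigid components. Applied to proteins, the same machinery
predicts which regions of a structure are rigid and which hinges allow
motion: atoms and their covalent neighborhoods become rigid bodies, bonds
become bars (5 for a rotatable single bond, 6 for a locked peptide or
double bond, fewer for weak contacts), and the (6,6) pebble game on the
resulting multigraph yields the rigid cluster decomposition.

`rigidkit` provides:

* a generic **(k,ℓ)-pebble game** on multigraphs (any k ≥ 1, 0 ≤ ℓ < 2k,
  plus an explicit opt-in for the non-matroidal Maxwell boundary ℓ = 2k),
  with rigid-component detection across the whole parameter range;
* independent **oracles** — brute-force sparsity checking and a numeric
  rigidity-matrix rank/DOF computation — used to cross-validate the game;
* a **molecular pipeline**: PDB parsing, covalent-bond assignment from
  residue templates, hydrogen bonds with Mayo-form energies, salt
  bridges, hydrophobic tethers and π interactions, conversion to a
  body-and-bar multigraph, rigid cluster decomposition, energy-ordered
  **bond dilution**, residue-level mapping and PyMOL visualization;
* **trajectory analysis**: per-frame rigid clusters over a multi-model
  PDB (or XTC via the optional MDAnalysis extra) with consistent cluster
  coloring across frames;
* deterministic **fixture generators** (Laman graphs via Henneberg
  construction, Erdős–Rényi and complete graphs, the double banana, an
  ideal α-helix and small toy molecules) so everything is testable
  offline.

## Worked example

Generate a minimally rigid (Laman) graph and play the (2,3) game:

```text
$ rigidkit fixtures graph laman -n 10 --seed 3 laman.graphml
wrote laman.graphml (10 vertices, 17 edges)
$ rigidkit pebble laman.graphml -k 2 -l 3 --components
category: tight
free pebbles: 3
accepted: 17  rejected: 0
component 1: 0 1 2 3 4 5 6 7 8 9
```

The graph has exactly 2·10 − 3 = 17 edges, every edge is accepted, and
three pebbles remain — the three trivial planar motions. The whole vertex
set is one rigid component: the graph is minimally rigid.

Molecular analysis of an ideal 10-residue polyalanine α-helix:

```text
$ rigidkit fixtures pdb helix --n-res 10 helix.pdb
wrote helix.pdb
$ rigidkit pdb helix.pdb --out helix.xml --residue-json helix.json
atoms: 60
non-trivial components at threshold 0.0: 1
  component 0: 54 atoms
dilution steps: 3
```

The six i → i+4 backbone hydrogen bonds (≈ −3.46 kcal/mol each from the
Mayo-form potential) lock the helix into a single 54-atom rigid cluster
covering residues 1–9; only the flexible chain termini stay outside.
The dilution series in `helix.xml` records how the nine isolated peptide
units merge into that single cluster as hydrogen bonds are inserted
strongest-first. Downstream:

```text
$ rigidkit residue helix.xml residues.json   # residue-level clusters
1 residue-level component(s) -> residues.json
$ rigidkit pymol helix.xml helix.pdb view.pml  # PyMOL coloring script
wrote view.pml
```

Per-frame analysis of a trajectory (multi-model PDB or `.xtc`):

```text
$ rigidkit xtc topo.pdb traj.pdb --out-dir frames
analyzed 3 frame(s) -> frames
```

which writes one results XML per frame plus `tracking.tsv` linking
clusters across frames by consistent color ids.

The same functionality is available as a library; see the docstrings in
`rigidkit.pebble`, `rigidkit.pipeline` and `rigidkit.trajectory`, and the
scientific notes in `docs/methods.md`.

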