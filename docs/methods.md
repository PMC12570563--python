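# Methods

This note records the model, the algorithmic choices, the tunable
parameters (with units and defaults), and the known limitations of
`rigidkit`.

## 1. Sparsity, tightness, and the pebble game

A multigraph is **(k,ℓ)-sparse** if every nonempty edge subset E′
satisfies |E′| ≤ k·|V(E′)| − ℓ, and **(k,ℓ)-tight** if in addition
|E| = k·|V| − ℓ. For 0 ≤ ℓ < 2k the sparse edge sets form the independent
sets of a matroid, which is what makes a greedy edge-by-edge algorithm
correct and its outcome independent of insertion order.

The pebble game maintains k pebbles per vertex and a directed placement
of accepted edges. An edge (u,v) is accepted iff ℓ+1 pebbles can be
gathered on {u,v}; gathering moves a pebble backwards along a directed
path, reversing it. Accepted edges are exactly a maximal sparse subset,
so the final state classifies the input as

* `tight` — all edges accepted and exactly ℓ free pebbles remain,
* `sparse` — all accepted, more than ℓ pebbles free,
* `spanning` — some edges rejected but the accepted set is tight
  (rigid with redundancy),
* `other` — everything else.

Loops are allowed only when ℓ < k (at most k − ℓ copies), matching the
matroid; a loop otherwise raises an error.

**Maxwell boundary ℓ = 2k.** The classical 3-dimensional count
|E| = 3|V| − 6 corresponds to (3,6), which lies *outside* the matroidal
range. Constructing `SparsityParams(k, 2k)` therefore raises an error
unless `boundary=True` is passed explicitly. In boundary mode the
acceptance rule gathers ℓ pebbles (not ℓ+1), reproducing Maxwell
counting; component detection is refused because maximal "tight" sets
are not well defined there. The package's canonical demonstration is the
double banana: 8 vertices, 18 = 3·8 − 6 edges, accepted in full by the
boundary game, while the numeric rigidity matrix shows one internal
degree of freedom — the well-known failure of naive 3D counting.

## 2. Rigid components

After an accepted edge (u,v), if ℓ+1 pebbles can no longer be gathered
on {u,v}, a new rigid (vertex-maximal tight) component has formed. We
compute it as the **complement of reverse reachability**: the component
is the set of vertices that cannot reach, along the directed placement,
any free pebble held outside {u,v}. For ℓ ≤ k this reduces to the
familiar "vertices reached from {u,v}" rule, but unlike that rule it
remains correct in the upper range k < ℓ < 2k, where distinct components
may share a single vertex (e.g. two triangles hinged at a point under
(3,4)). The proof sketch: a set S is closed and tight iff the edges
inside S absorb exactly k|S| − ℓ pebbles; any vertex with a directed
path to an external free pebble could donate a pebble and therefore lies
outside every tight set containing {u,v}.

A component index maintains the current family: a newly detected
component absorbs previous ones that share at least two vertices or are
subsets, and a same-component query short-circuits pebble searches for
edges inside a known component (they are redundant by definition).

## 3. Numeric oracles

Two independent checks guard the combinatorial core:

* **Brute force**: enumerate all vertex subsets (inputs ≤ 15 vertices)
  and verify the sparsity counts directly.
* **Rigidity matrix**: embed the graph with random coordinates (two
  independent samples, seeded), build the |E| × D|V| matrix with rows
  ±(x_u − x_v), and compute DOF = D·n − rank − trivial(n,D), where
  trivial(n,D) counts rigid-body motions of an n-point configuration
  (C(D+1,2) capped for degenerate point counts). Rank uses an SVD with a
  relative threshold of 1e−9; taking the max rank over the two samples
  protects against an unlucky non-generic embedding.

For (2,3) the game's tight/spanning verdict coincides with DOF = 0 in
2D on every random graph tested (this equivalence is asserted in the
test suite over hundreds of instances).

## 4. Molecular model

**Bodies.** Every atom with ≥ 2 covalent neighbors becomes a rigid body
(the atom plus its bonded neighborhood: fixed bond lengths and angles
make that unit rigid). Valency-1 atoms (hydrogens, carbonyl oxygens) are
subsumed into their partner's body. Atoms with no covalent partner are
excluded with a warning.

**Bars.** Bonds between bodies contribute bars, capped at 6 per body
pair (a 7th bar is never independent in the (6,6) game):

| interaction | bars | energy (kcal/mol) |
|---|---|---|
| covalent single bond, disulfide | 5 | 0 (always present) |
| covalent double/triple, peptide/amide | 6 | 0 (always present) |
| hydrogen bond | 5 | Mayo-form, ≤ 0 |
| salt bridge | 5 | −10 (fixed) |
| hydrophobic tether | 3 | −0.5 (vdW mode) or Lennard-Jones |
| π stacking / π–cation | 3 | −1.5 / −2.0 (fixed) |

A single bond leaves exactly one torsional degree of freedom
(6·2 − 6 − 5 = 1 for an isolated two-body system); a double or peptide
bond locks the pair. These two facts are asserted on toy molecules.

**Covalent detection** runs in phases: residue templates (all 20 amino
acids, nucleotides, bond orders for aromatic rings and carbonyls),
peptide C–N and nucleic O3′–P links between consecutive residues,
disulfides (SG–SG ≤ 2.5 Å), a covalent-radius distance fallback for
unknown residues (Cordero radii + 0.40 Å tolerance), and attachment of
stray hydrogens to their nearest heavy atom (≤ 1.6 Å).

**Hydrogen bonds** use a Mayo-form potential
E = V₀ (5(d₀/d)¹² − 6(d₀/d)¹⁰) · F(θ, φ) with V₀ = 8 kcal/mol,
d₀ = 2.8 Å, a donor–acceptor gate of 4.6 Å and a D–H···A angle gate of
100°; F depends on donor/acceptor hybridization (sp² reference angle
120°, sp³ 109.5°, with a cos²θ term and a damping factor near
linearity). Donors are N/O/S bearing a hydrogen; acceptors are O/S and
nitrogens without hydrogens and with ≤ 2 heavy neighbors. Structures
without polar hydrogens degrade to a distance-only mode (3.5 Å, 4.0 Å
when sulfur is involved) with an explicit warning. Salt bridges are
geometric (charged-group heavy atoms ≤ 4.0 Å) and supersede a hydrogen
bond on the same atom pair.

**Hydrophobic tethers** connect C/S atoms more than three covalent bonds
apart, either within the sum of van-der-Waals radii + 0.25 Å (vdW mode;
assigned a fixed −0.5 kcal/mol so the dilution order stays total) or
wherever a 12-6 Lennard-Jones energy is ≤ −0.05 kcal/mol (LJ mode).

**π systems** come from ring templates (PHE/TYR/TRP/HIS and the nucleic
bases): stacking when ring centers are ≤ 5.5 Å with normals within 30°
(or T-shaped, 60–90°), π–cation for LYS/ARG cations ≤ 6.0 Å near the
ring axis.

All distance searches use k-d trees; detection is O(n log n) in the atom
count for bounded-density structures.

## 5. Phased pre-cover

Bars of the covalent skeleton need no pebble searches: a deterministic
BFS forest over the covalent body graph is oriented child-to-parent with
at most ℓ − 1 = 5 bars per tree link placed directly. Every body then
retains ≥ 1 pebble, so the placement is a legal, reachable game state.
Only ring closures, sixth copies, and non-covalent bars (queued by
ascending energy, i.e. strongest first) are inserted through the normal
game. The final rank and component family equal a cold-start run — this
equivalence is asserted in the tests.

## 6. Dilution and trajectories

**Dilution** plays a single game: covalent bars first (the baseline,
e.g. the nine isolated peptide units of a 10-residue helix), then every
non-covalent bar in ascending energy order, snapshotting the component
family whenever it changes. Matroid order-independence makes each
prefix identical to a direct run at the corresponding energy threshold,
so one run yields the entire rigidity-vs-threshold profile; read
weakest-to-strongest it simulates thermal unfolding. The largest
component size is non-decreasing along the series.

**Trajectories** fix the covalent chemistry from the topology structure
and re-detect the geometric (non-covalent) interactions on every frame,
replaying the component game per frame. Frames are pure functions of
(topology, coordinates, config); only the cluster coloring threads state
between frames, matching clusters greedily by maximal Jaccard overlap so
a persisting cluster keeps its color and new clusters get fresh ones.
Native input is a multi-model PDB; XTC is read through an optional
MDAnalysis adapter.

**Residue level**: a residue joins a cluster when the majority of its
heavy atoms belong to it (ties resolved by the backbone representative,
CA or C1′); clusters spanning fewer than two residues are suppressed.

## 7. Synthetic fixtures and their limits

All test inputs are generated programmatically: Laman graphs by random
Henneberg constructions (type I/II steps, giving exactly 2n − 3 edges by
construction), the double banana, and an ideal polyalanine α-helix built
from internal coordinates (φ = −57°, ψ = −47°, ω = 180°) via sequential
NeRF placement. The helix reproduces the canonical i → i+4 backbone
hydrogen-bond register (N···O ≈ 3.1 Å) but is idealized: no side-chain
diversity, no solvent, no thermal noise. Toy molecules (single/double
bond, branched) probe the bar rules in isolation. Real structures are
supported through standard PDB input; the parser keeps the first model,
primary alternate locations, and drops water by default.

## 8. Numerical and determinism choices

* Pebble searches visit neighbors in ascending vertex order; all
  generators take explicit seeds — identical inputs give byte-identical
  outputs (XML/JSON/PyMOL writers sort members and avoid timestamps).
* SVD rank threshold 1e−9 (relative); energies are stored in results XML
  via `repr(float)` for exact round-trips.
* Energies are kcal/mol, distances Å, angles degrees throughout.

## 9. Limitations

* Generic rigidity only: the combinatorial result holds for almost all
  geometric realizations; special positions (collinear bananas, flat
  rings) can be more flexible than the generic count suggests. The
  numeric oracle samples random embeddings and can in principle miss
  non-generic degeneracies.
* The (6,6) body-and-bar model treats bond lengths/angles as exact
  constraints and weak contacts as rigid bars; it predicts which motions
  are *possible*, not their amplitudes or time scales.
* Interaction energies besides hydrogen bonds are coarse constants;
  hydrophobic and π parameters are geometric heuristics.
* Component detection is unavailable at the Maxwell boundary ℓ = 2k
  (not well defined there); use the numeric oracle for such cases.
* The PDB parser handles the fixed-column subset used in practice
  (ATOM/HETATM/MODEL/ENDMDL, alternate locations, insertion codes); it
  does not read mmCIF.
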