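"""End-to-end molecular rigidity workflow.

``run_rigidity`` plays the (6,6) component pebble game on the
body-and-bar multigraph of a structure (phased pre-cover, then covalent
leftovers, then the non-covalent bars at or below the energy threshold)
and maps rigid components of bodies back to atoms.  ``dilution``
inserts *all* non-covalent bars strongest-to-weakest in a single game
run, snapshotting the component decomposition whenever it changes —
read in reverse this simulates thermal unfolding, and any threshold's
decomposition can be read off the series without re-running the game.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bodybar import BodyBarGraph, build_body_bar_graph, phased_precover
from .interactions import COVALENT_KINDS, BondRecord, InteractionConfig, MolecularGraph
from .pebble import ComponentIndex, GameSummary, SparsityParams, _summarize
from .templates import NUCLEOTIDES

__all__ = [
    "AtomComponent",
    "DilutionStep",
    "DilutionSeries",
    "run_rigidity",
    "dilution",
    "to_residue_level",
    "consistent_colors",
]


@dataclass(frozen=True)
class AtomComponent:
    """A rigid component mapped to atom level.

    Atoms are the union, over member bodies, of the body atom and its
    covalent neighbors; peripheral atoms may belong to several
    components.
    """

    id: int
    atom_refs: frozenset
    source_bodies: frozenset


@dataclass
class DilutionStep:
    index: int              # position in the non-covalent insertion order
    last_bond: BondRecord
    energy: float
    components: list        # AtomComponents after this insertion


@dataclass
class DilutionSeries:
    baseline: list          # components with covalent bonds only
    steps: list

    def at_threshold(self, energy: float) -> list:
        """Component decomposition including all bonds with energy <= threshold."""
        current = self.baseline
        for step in self.steps:
            if step.energy <= energy:
                current = step.components
            else:
                break
        return current


def _atom_components(index: ComponentIndex, mol: MolecularGraph) -> list:
    adj = mol.covalent_adjacency()
    out = []
    for i, comp in enumerate(index.nontrivial()):
        atoms: set = set()
        for body in comp.vertex_ids:
            atoms.add(body)
            atoms |= adj[body]
        out.append(
            AtomComponent(id=i, atom_refs=frozenset(atoms), source_bodies=comp.vertex_ids)
        )
    return out


def _play_entries(g, index: ComponentIndex, entries) -> list:
    """Insert queued bars copy-by-copy with the component extension."""
    rejected = []
    for q in entries:
        for _ in range(q.count):
            if index.same_component(q.u, q.v):
                rejected.append((q.u, q.v))
                continue
            res = g.try_insert_edge(q.u, q.v, 1)
            if res.rejected:
                rejected.append((q.u, q.v))
                continue
            comp = g.detect_component(q.u, q.v)
            if comp is not None:
                index.register(comp)
    return rejected


def run_rigidity(
    mol: MolecularGraph, config: InteractionConfig | None = None
) -> tuple[list, GameSummary]:
    """The (6,6) component game at the configured energy threshold."""
    cfg = config or InteractionConfig()
    if len(mol.atoms) == 0:
        raise ValueError("empty structure")
    bbg = build_body_bar_graph(mol)
    g, queue = phased_precover(bbg, SparsityParams(6, 6))
    index = ComponentIndex()
    rejected = _play_entries(
        g,
        index,
        (
            q
            for q in queue
            if q.bond.kind in COVALENT_KINDS or q.bond.energy <= cfg.threshold
        ),
    )
    return _atom_components(index, mol), _summarize(g, rejected)


def dilution(mol: MolecularGraph, config: InteractionConfig | None = None) -> DilutionSeries:
    """Single-run dilution analysis over all quantified non-covalent bonds.

    Covalent bars first, then every non-covalent bar from the strongest
    (most negative) to the weakest; a step is recorded whenever the
    component family changes.  The matroid property of the sparse-graph
    family makes the final decomposition independent of this order, so
    prefix decompositions are exactly the per-threshold results.
    """
    cfg = config or InteractionConfig()
    if len(mol.atoms) == 0:
        raise ValueError("empty structure")
    bbg = build_body_bar_graph(mol)
    g, queue = phased_precover(bbg, SparsityParams(6, 6))
    index = ComponentIndex()
    covalent = [q for q in queue if q.bond.kind in COVALENT_KINDS]
    noncov = [q for q in queue if q.bond.kind not in COVALENT_KINDS]
    _play_entries(g, index, covalent)

    def family():
        return {c.vertex_ids for c in index.nontrivial()}

    baseline = _atom_components(index, mol)
    prev = family()
    steps = []
    for i, q in enumerate(noncov):
        _play_entries(g, index, [q])
        fam = family()
        if fam != prev:
            steps.append(
                DilutionStep(
                    index=i,
                    last_bond=q.bond,
                    energy=q.bond.energy,
                    components=_atom_components(index, mol),
                )
            )
            prev = fam
    return DilutionSeries(baseline=baseline, steps=steps)


def to_residue_level(components: list, mol: MolecularGraph) -> list:
    """Map atom components to residue-level components by majority vote.

    A residue joins a component when the majority of its heavy atoms are
    members; an exact tie is decided by membership of the backbone
    representative (CA for amino acids, C1' for nucleotides).  Residue
    components of fewer than 2 residues are suppressed.  Returns a list
    of sorted (chain, res_seq, insertion) tuples per component.
    """
    atoms = mol.atoms
    res_atoms: dict = {}
    for idx, row in atoms.iterrows():
        if row["element"] == "H":
            continue
        key = (row["chain"], int(row["res_seq"]), row["insertion"])
        res_atoms.setdefault(key, []).append(idx)
    out = []
    for comp in components:
        members = []
        for key, idxs in res_atoms.items():
            inside = sum(1 for i in idxs if i in comp.atom_refs)
            if 2 * inside > len(idxs):
                members.append(key)
            elif 2 * inside == len(idxs):
                backbone = "C1'" if atoms.at[idxs[0], "res_name"] in NUCLEOTIDES else "CA"
                rep = [i for i in idxs if atoms.at[i, "name"] == backbone]
                if rep and rep[0] in comp.atom_refs:
                    members.append(key)
        if len(members) >= 2:
            out.append(sorted(members))
    out.sort(key=lambda m: (-len(m), m))
    return out


def consistent_colors(snapshots: list) -> dict:
    """Thread stable color ids through a sequence of component families.

    Components of consecutive snapshots are matched greedily by maximal
    Jaccard overlap of their member sets; matched components inherit the
    color, unmatched ones receive fresh colors, and retired colors are
    never reused.  Returns ``(snapshot_index, member_frozenset) -> color``.
    """
    colors: dict = {}
    next_color = 0
    prev: list = []
    for t, family in enumerate(snapshots):
        members = [frozenset(_members(c)) for c in family]
        assigned: dict = {}
        if prev:
            pairs = []
            for m in members:
                for pm, pcolor in prev:
                    inter = len(m & pm)
                    if inter:
                        union = len(m | pm)
                        pairs.append((inter / union, m, pm, pcolor))
            pairs.sort(key=lambda p: (-p[0], sorted(p[1]), sorted(p[2])))
            used_prev = set()
            for score, m, pm, pcolor in pairs:
                if m in assigned or pcolor in used_prev:
                    continue
                assigned[m] = pcolor
                used_prev.add(pcolor)
        for m in members:
            if m not in assigned:
                assigned[m] = next_color
                next_color += 1
        for m, c in assigned.items():
            colors[(t, m)] = c
        prev = list(assigned.items())
    return colors


def _members(component) -> frozenset:
    if isinstance(component, AtomComponent):
        return component.atom_refs
    if isinstance(component, frozenset):
        return component
    return frozenset(component)
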