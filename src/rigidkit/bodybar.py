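"""From the atom-level interaction graph to the body-and-bar multigraph.

Each atom with at least two covalent neighbors becomes a rigid *body*
(the atom plus its bonded neighborhood moves as a unit once bond lengths
and angles are fixed).  Valency-1 atoms (hydrogens, carbonyl oxygens,
halogens) are subsumed into their unique partner's body.  Bonds between
bodies contribute bars: 5 for a single bond (torsion free), 6 for a
double/planar bond (locked), fewer for weak contacts.  The (6,6) pebble
game on this multigraph decides molecular rigidity.

The phased pre-cover exploits the known covalent skeleton: a spanning
forest of the covalent body graph is oriented child-to-parent with
l-1 = 5 bars per tree link placed directly — a reachable game state —
so only ring-closing bonds, 6th copies and non-covalent bars need
actual pebble searches.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

from .interactions import COVALENT_KINDS, BondRecord, MolecularGraph
from .pebble import PebbledGraph, SparsityParams

__all__ = ["BodyBarGraph", "QueuedBars", "build_body_bar_graph", "phased_precover"]

MAX_BARS = 6  # k*2 - l for the (6,6) game: more bars between a pair are never independent


@dataclass
class QueuedBars:
    """Bars between two bodies still to be inserted by the pebble game."""

    u: int
    v: int
    count: int
    bond: BondRecord  # the source bond (carries kind and energy)


@dataclass
class BodyBarGraph:
    bodies: set            # atom indices acting as rigid bodies
    bar_weight: dict       # (body, body) sorted pair -> bars (capped at MAX_BARS)
    provenance: dict       # pair -> list of contributing BondRecords
    host: dict             # atom index -> its host body (itself, or its unique partner)
    covalent_pairs: set    # pairs joined by at least one covalent-kind bond
    neighbors: dict        # body -> set of covalently linked bodies

    def atoms_of_body(self, body: int, covalent_adj: dict) -> set:
        return {body} | covalent_adj[body]


def build_body_bar_graph(mol: MolecularGraph) -> BodyBarGraph:
    """Collapse the atom graph into bodies and accumulate bar weights."""
    adj = mol.covalent_adjacency()
    bodies = {i for i, nbrs in adj.items() if len(nbrs) >= 2}
    isolated = [i for i, nbrs in adj.items() if not nbrs]
    if isolated:
        warnings.warn(
            f"{len(isolated)} atom(s) without covalent bonds excluded from the "
            "body-and-bar graph",
            stacklevel=2,
        )

    host: dict = {}
    for i, nbrs in adj.items():
        if i in bodies:
            host[i] = i
        elif len(nbrs) == 1:
            partner = next(iter(nbrs))
            host[i] = partner if partner in bodies else None
        else:
            host[i] = None

    bar_weight: dict = {}
    provenance: dict = {}
    covalent_pairs: set = set()
    neighbors: dict = {b: set() for b in bodies}

    def add_bars(u, v, bond, covalent):
        if u is None or v is None or u == v:
            return
        pair = (u, v) if u < v else (v, u)
        have = bar_weight.get(pair, 0)
        add = min(bond.bars, MAX_BARS - have)
        if add <= 0 and not covalent:
            return  # fully capped; weak contact adds nothing
        bar_weight[pair] = have + max(add, 0)
        provenance.setdefault(pair, []).append(bond)
        if covalent:
            covalent_pairs.add(pair)
            neighbors[pair[0]].add(pair[1])
            neighbors[pair[1]].add(pair[0])

    for bond in mol.bonds:
        if bond.kind in COVALENT_KINDS:
            # a bond incident to a valency-1 atom is subsumed in the body
            if bond.a in bodies and bond.b in bodies:
                add_bars(bond.a, bond.b, bond, covalent=True)
        else:
            add_bars(host.get(bond.a), host.get(bond.b), bond, covalent=False)

    return BodyBarGraph(
        bodies=bodies,
        bar_weight=bar_weight,
        provenance=provenance,
        host=host,
        covalent_pairs=covalent_pairs,
        neighbors=neighbors,
    )


def phased_precover(
    bbg: BodyBarGraph, params: SparsityParams | None = None
) -> tuple[PebbledGraph, list]:
    """Pre-place covalent bars along a spanning forest; queue the rest.

    Tree links carry up to l-1 bars oriented child-to-parent, so every
    body keeps at most l-1 outgoing copies — a legal pebble-game state
    reached without any searches.  Returned queue: leftover covalent
    bars (ring closures, 6th copies) first, then non-covalent bars
    ordered by energy ascending (strongest first; ties by atom pair).
    The final component decomposition after playing the queue equals a
    cold-start game on all bars.
    """
    params = params or SparsityParams(6, 6)
    if not bbg.bodies:
        raise ValueError("body-and-bar graph has no bodies")
    g = PebbledGraph(sorted(bbg.bodies), params)
    precovered: dict = {}

    # deterministic BFS forest over the covalent skeleton
    visited: set = set()
    for root in sorted(bbg.bodies):
        if root in visited:
            continue
        visited.add(root)
        dq = deque([root])
        while dq:
            parent = dq.popleft()
            for child in sorted(bbg.neighbors[parent]):
                if child in visited:
                    continue
                visited.add(child)
                dq.append(child)
                pair = (parent, child) if parent < child else (child, parent)
                total = sum(
                    b.bars for b in bbg.provenance[pair] if b.kind in COVALENT_KINDS
                )
                pre = min(total, params.l - 1, g.pebbles[child])
                g.pebbles[child] -= pre
                g._out[child][parent] = g._out[child].get(parent, 0) + pre
                precovered[pair] = pre

    queue: list = []
    cov_entries = []
    noncov_entries = []
    for pair in sorted(bbg.bar_weight):
        placed = precovered.get(pair, 0)
        for bond in bbg.provenance[pair]:
            if bond.kind in COVALENT_KINDS:
                take = min(bond.bars, MAX_BARS)
                if placed >= take:
                    placed -= take
                    continue
                left = take - placed
                placed = 0
                cov_entries.append(QueuedBars(pair[0], pair[1], left, bond))
    total_placed = {p: precovered.get(p, 0) for p in bbg.bar_weight}
    for pair in sorted(bbg.bar_weight):
        budget = bbg.bar_weight[pair] - total_placed[pair] - sum(
            q.count for q in cov_entries if (q.u, q.v) == pair
        )
        for bond in bbg.provenance[pair]:
            if bond.kind in COVALENT_KINDS:
                continue
            take = min(bond.bars, budget)
            if take > 0:
                noncov_entries.append(QueuedBars(pair[0], pair[1], take, bond))
                budget -= take
    noncov_entries.sort(key=lambda q: (q.bond.energy, q.u, q.v))
    queue = cov_entries + noncov_entries
    return g, queue
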