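"""Deterministic generators for graphs and small molecular structures.

Everything the test-suite and the benchmark reproduction need is built
here programmatically: random Laman graphs (Henneberg construction),
Erdős–Rényi and complete graphs, the double-banana counterexample, an
ideal polyalanine α-helix, toy molecules exercising the bar rules, and
a stacked base pair for π-interaction detection.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import math
import random
from itertools import combinations

import numpy as np

from .pebble import Multigraph

__all__ = [
    "laman_graph",
    "er_graph",
    "complete_graph",
    "double_banana",
    "ideal_helix_pdb",
    "toy_molecule_pdb",
    "stacked_pair_pdb",
]

# probability of a Henneberg type-I move (vertex addition) vs type-II
# (edge split); any mix preserves (2,3)-tightness
_HENNEBERG_TYPE1_P = 0.7


def laman_graph(n: int, seed: int = 0) -> Multigraph:
    """A random (2,3)-tight (Laman) graph on ``n`` vertices, 2n-3 edges.

    Built from K3 by random Henneberg moves: type I adds a new vertex
    joined to two existing vertices; type II removes an existing edge uv
    and adds a new vertex joined to u, v and a third vertex w.  Both
    moves preserve Laman-ness, so the output is tight by construction.
    """
    if n < 3:
        raise ValueError("Laman graphs need n >= 3")
    rng = random.Random(seed)
    edges = {(0, 1), (0, 2), (1, 2)}
    for z in range(3, n):
        if z == 3 or rng.random() < _HENNEBERG_TYPE1_P:
            u, v = rng.sample(range(z), 2)
            edges.add((min(u, z), max(u, z)))
            edges.add((min(v, z), max(v, z)))
        else:
            u, v = rng.choice(sorted(edges))
            w = rng.choice([x for x in range(z) if x not in (u, v)])
            edges.discard((u, v))
            for x in (u, v, w):
                edges.add((min(x, z), max(x, z)))
    assert len(edges) == 2 * n - 3
    return Multigraph(list(range(n)), [(u, v, 1) for u, v in sorted(edges)])


def er_graph(n: int, p: float, seed: int = 0) -> Multigraph:
    """An Erdős–Rényi G(n, p) simple graph."""
    if not (0 <= p <= 1):
        raise ValueError("edge probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return Multigraph(
        list(range(n)),
        [(int(a), int(b), 1) for a, b in zip(iu[mask], ju[mask])],
    )


def complete_graph(n: int) -> Multigraph:
    return Multigraph(list(range(n)), [(u, v, 1) for u, v in combinations(range(n), 2)])


def double_banana() -> Multigraph:
    """The 8-vertex, 18-edge double banana.

    Two copies of K5 minus an edge, glued along the two endpoints of the
    missing edge.  Satisfies 3|V|-6 counting ((3,6)-tight) yet every
    generic 3D embedding retains one internal motion — the canonical
    counterexample to naive 3D constraint counting.
    """
    edges = []
    for banana in ({0, 1, 2, 3, 4}, {0, 1, 5, 6, 7}):
        for u, v in combinations(sorted(banana), 2):
            if (u, v) != (0, 1):
                edges.append((u, v, 1))
    return Multigraph(list(range(8)), edges)


# ---------------------------------------------------------------------------
# Molecular fixtures
# ---------------------------------------------------------------------------


def _pdb_line(serial, name, res_name, chain, res_seq, xyz, element, hetero=False):
    record = "HETATM" if hetero else "ATOM"
    # PDB atom-name column convention: 1/2-char element names start in col 14
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field} {res_name:>3s} {chain}{res_seq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _nerf(a, b, c, r, theta_deg, tau_deg):
    """Place atom d bonded to c with |cd|=r, angle(b,c,d)=theta, dihedral(a,b,c,d)=tau."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(tau),
            r * math.sin(theta) * math.sin(tau),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_helix_pdb(n_res: int, chain: str = "A") -> str:
    """A polyalanine α-helix (φ=-57°, ψ=-47°, ω=180°) as PDB text.

    Backbone N, CA, C, O plus the amide hydrogen H and the side-chain
    CB, built from ideal internal coordinates.  The geometry places the
    classic i→i+4 backbone hydrogen bonds (N-H of residue i+4 donating
    to O of residue i).
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    phi, psi, omega = -57.0, -47.0, 180.0
    coords: list[dict] = []
    for i in range(n_res):
        res: dict = {}
        if i == 0:
            res["N"] = np.array([0.0, 0.0, 0.0])
            res["CA"] = np.array([1.458, 0.0, 0.0])
            ang = math.radians(180.0 - 111.2)
            res["C"] = res["CA"] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
            # amide H: in-plane, roughly opposite CA
            res["H"] = _nerf(res["C"], res["CA"], res["N"], 1.01, 118.2, 180.0)
        else:
            prev = coords[i - 1]
            res["N"] = _nerf(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
            res["CA"] = _nerf(prev["CA"], prev["C"], res["N"], 1.458, 121.7, omega)
            res["C"] = _nerf(prev["C"], res["N"], res["CA"], 1.525, 111.2, phi)
            res["H"] = _nerf(prev["CA"], prev["C"], res["N"], 1.01, 119.5, 0.0)
        res["O"] = _nerf(res["N"], res["CA"], res["C"], 1.231, 120.8, psi + 180.0)
        res["CB"] = _nerf(res["C"], res["N"], res["CA"], 1.521, 110.4, 122.5)
        coords.append(res)
    lines = []
    serial = 1
    for i, res in enumerate(coords):
        for name in ("N", "CA", "C", "O", "CB", "H"):
            element = name[0]
            lines.append(_pdb_line(serial, name, "ALA", chain, i + 1, res[name], element))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# tetrahedral unit directions for a carbon bonded along +x
_TET = [
    (-1 / 3, 2 * math.sqrt(2) / 3, 0.0),
    (-1 / 3, -math.sqrt(2) / 3, math.sqrt(2 / 3)),
    (-1 / 3, -math.sqrt(2) / 3, -math.sqrt(2 / 3)),
]


def toy_molecule_pdb(kind: str) -> str:
    """Minimal heavy-atom + hydrogen geometries exercising bar multiplicities.

    * ``single_bond`` — an ethane-like C-C with 3 H each: one residual
      torsional degree of freedom, (6,6)-sparse.
    * ``double_bond`` — an ethene-like C=C with 2 H each: rigid,
      (6,6)-tight.
    * ``branched`` — a neopentane-like C(C)(C)(C) core: every carbon a
      rigid body.
    """
    atoms: list[tuple[str, str, np.ndarray]] = []  # (name, element, xyz)
    if kind == "single_bond":
        res = "ETH"
        c1, c2 = np.zeros(3), np.array([1.54, 0.0, 0.0])
        atoms += [("C1", "C", c1), ("C2", "C", c2)]
        for j, d in enumerate(_TET):
            atoms.append((f"H1{j+1}", "H", c1 + 1.09 * np.array(d)))
            atoms.append((f"H2{j+1}", "H", c2 - 1.09 * np.array(d)))
    elif kind == "double_bond":
        res = "ETE"
        c1, c2 = np.zeros(3), np.array([1.33, 0.0, 0.0])
        atoms += [("C1", "C", c1), ("C2", "C", c2)]
        for j, s in enumerate((1.0, -1.0)):
            atoms.append((f"H1{j+1}", "H", c1 + 1.09 * np.array([-0.5, s * 0.866, 0.0])))
            atoms.append((f"H2{j+1}", "H", c2 + 1.09 * np.array([0.5, s * 0.866, 0.0])))
    elif kind == "branched":
        res = "BRN"
        c0 = np.zeros(3)
        dirs = [np.array([1.0, 0.0, 0.0])] + [np.array(d) * -1 for d in _TET]
        atoms.append(("C0", "C", c0))
        for j, d in enumerate(dirs):
            cj = c0 + 1.54 * d
            atoms.append((f"C{j+1}", "C", cj))
            # three hydrogens completing each methyl, pointing outward
            perp = np.cross(d, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(d, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            perp2 = np.cross(d, perp)
            for h in range(3):
                ang = 2 * math.pi * h / 3
                hd = d * (1 / 3) + (math.cos(ang) * perp + math.sin(ang) * perp2) * (
                    2 * math.sqrt(2) / 3
                )
                atoms.append((f"H{j+1}{h+1}", "H", cj + 1.09 * hd))
    else:
        raise ValueError(f"unknown toy molecule kind {kind!r}")
    lines = [
        _pdb_line(i + 1, name, res, "A", 1, xyz, el, hetero=True)
        for i, (name, el, xyz) in enumerate(atoms)
    ]
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def stacked_pair_pdb(separation: float = 3.4) -> str:
    """Two parallel six-membered base rings (adenine numbering), stacked.

    Emitted as two RNA adenosine residues carrying only their pyrimidine
    ring atoms; the rings sit ``separation`` Å apart with aligned
    normals — the textbook π-stacking geometry of nucleic-acid bases.
    """
    ring_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    lines = []
    serial = 1
    for res_seq, z in ((1, 0.0), (2, separation)):
        for j, name in enumerate(ring_names):
            ang = 2 * math.pi * j / 6
            xyz = np.array([1.39 * math.cos(ang), 1.39 * math.sin(ang), z])
            lines.append(_pdb_line(serial, name, "A", "A", res_seq, xyz, name[0]))
            serial += 1
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"
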