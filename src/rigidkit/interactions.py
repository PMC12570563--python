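"""Detection of covalent bonds and non-covalent contacts in an atom table.

The covalent skeleton is built in phases: per-residue templates (bond
orders included), inter-residue backbone links (peptide C-N, nucleic
O3'-P), disulfides, a distance fallback from covalent radii for anything
the templates missed, and hydrogen attachment.  Non-covalent detectors
quantify hydrogen bonds and salt bridges (Mayo-form potential),
hydrophobic tethers (van-der-Waals surface overlap or a Lennard-Jones
12-6 energy), and π-stacking / π-cation geometry.

All bond records carry the number of bars they contribute to the
body-and-bar multigraph: 5 for a single covalent bond, hydrogen bond,
salt bridge or disulfide (one torsional degree of freedom left), 6 for
double/triple/planar-amide bonds (locked), and a configurable smaller
number (default 3) for the weaker hydrophobic and π contacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pdbio import coords_array
from .templates import (
    AROMATIC_RINGS,
    CHARGED_NEGATIVE,
    CHARGED_POSITIVE,
    COVALENT_RADII,
    COVALENT_TOLERANCE,
    LJ_PARAMS,
    PI_CATIONS,
    RESIDUE_TEMPLATES,
    VDW_RADII,
)

__all__ = [
    "BondRecord",
    "InteractionConfig",
    "MolecularGraph",
    "detect_covalent",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_pi",
    "build_molecular_graph",
]

COVALENT_KINDS = {
    "covalent_single", "covalent_double", "covalent_triple", "peptide", "disulfide",
}
#: bar multiplicity by bond kind (hydrophobic/π read from the config instead)
BARS_BY_KIND = {
    "covalent_single": 5,
    "covalent_double": 6,
    "covalent_triple": 6,
    "peptide": 6,
    "disulfide": 5,
    "hbond": 5,
    "salt_bridge": 5,
}


@dataclass(frozen=True)
class BondRecord:
    """One typed edge of the atom-level interaction graph.

    ``a``/``b`` are integer row labels of the atom table; ``energy`` is
    0 for covalent kinds and <= 0 (kcal/mol) for quantified contacts.
    """

    a: int
    b: int
    kind: str
    energy: float = 0.0
    bars: int = 5

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("bond endpoints must differ")
        if not (1 <= self.bars <= 6):
            raise ValueError("bars must lie in [1, 6]")

    @property
    def key(self) -> tuple:
        return (min(self.a, self.b), max(self.a, self.b))


@dataclass
class InteractionConfig:
    """Tunable parameters of the interaction model (distances in Å, energies kcal/mol)."""

    # hydrogen bonds (Mayo-form potential)
    hbond_v0: float = 8.0
    hbond_d0: float = 2.8
    hbond_distance_cutoff: float = 4.6     # donor-acceptor heavy-atom gate
    hbond_angle_min: float = 100.0         # minimum D-H...A angle, degrees
    hbond_emit_threshold: float = 0.0      # only bonds at or below this energy are emitted
    fallback_hbond_cutoff: float = 3.5     # distance-only mode (no hydrogens)
    fallback_hbond_cutoff_s: float = 4.0   # ... when a sulfur partner is involved
    # salt bridges
    salt_bridge_cutoff: float = 4.0
    salt_bridge_energy: float = -10.0
    # hydrophobic tethers
    hydrophobic_mode: str = "vdw"          # "vdw" or "lj"
    hydrophobic_slack: float = 0.25
    hydrophobic_energy: float = -0.5       # assigned energy in vdw mode
    lj_cutoff: float = -0.05
    hydrophobic_bars: int = 3
    # π interactions
    pi_bars: int = 3
    pi_stack_distance: float = 5.5
    pi_stack_angle: float = 30.0
    pi_t_angle: tuple = (60.0, 90.0)
    pi_cation_distance: float = 6.0
    pi_cation_angle: float = 60.0
    pi_stack_energy: float = -1.5
    pi_cation_energy: float = -2.0
    # rigidity stage
    threshold: float = 0.0                 # include contacts with energy <= threshold
    hydrophobic_enabled: bool = True
    pi_enabled: bool = True


@dataclass
class MolecularGraph:
    """Atom-level interaction graph: atom table plus typed bond list."""

    atoms: pd.DataFrame
    bonds: list

    def covalent_bonds(self) -> list:
        return [b for b in self.bonds if b.kind in COVALENT_KINDS]

    def noncovalent_bonds(self) -> list:
        return [b for b in self.bonds if b.kind not in COVALENT_KINDS]

    def covalent_adjacency(self) -> dict:
        adj: dict = {i: set() for i in self.atoms.index}
        for b in self.covalent_bonds():
            adj[b.a].add(b.b)
            adj[b.b].add(b.a)
        return adj


def _residue_groups(atoms: pd.DataFrame):
    """Residues in file order as (key, res_name, name->index mapping)."""
    groups = []
    for key, sub in atoms.groupby(
        ["chain", "res_seq", "insertion", "res_name"], sort=False
    ):
        name_map = {}
        for idx, row in sub.iterrows():
            name_map.setdefault(row["name"], idx)  # first wins (alt-locs already filtered)
        groups.append((key, key[3], name_map, sub))
    return groups


def _order_kind(order: int) -> str:
    return {1: "covalent_single", 2: "covalent_double", 3: "covalent_triple"}[order]


def detect_covalent(atoms: pd.DataFrame, templates: dict | None = None) -> list:
    """Covalent bond detection: templates, backbone links, disulfides, fallback."""
    templates = RESIDUE_TEMPLATES if templates is None else templates
    xyz = coords_array(atoms)
    pos = {idx: xyz[i] for i, idx in enumerate(atoms.index)}
    bonds: list = []
    bonded: set = set()

    def add(a, b, kind, bars=None):
        key = (min(a, b), max(a, b))
        if key in bonded:
            return
        bonded.add(key)
        bonds.append(BondRecord(a, b, kind, 0.0, BARS_BY_KIND[kind] if bars is None else bars))

    groups = _residue_groups(atoms)

    # (1) intra-residue template bonds
    unknown = set()
    for _, res_name, name_map, _sub in groups:
        tmpl = templates.get(res_name)
        if tmpl is None:
            unknown.add(res_name)
            continue
        for n1, n2, order in tmpl:
            if n1 in name_map and n2 in name_map:
                add(name_map[n1], name_map[n2], _order_kind(order))
    if unknown:
        warnings.warn(
            f"no template for residue(s) {sorted(unknown)}; relying on distance fallback",
            stacklevel=2,
        )

    # (2) inter-residue backbone links between consecutive residues of a chain
    for (k1, r1, m1, _), (k2, r2, m2, _) in zip(groups, groups[1:]):
        if k1[0] != k2[0]:  # chain change
            continue
        if "C" in m1 and "N" in m2:
            if np.linalg.norm(pos[m1["C"]] - pos[m2["N"]]) <= 1.8:
                add(m1["C"], m2["N"], "peptide")  # planar partial double bond
        if "O3'" in m1 and "P" in m2:
            if np.linalg.norm(pos[m1["O3'"]] - pos[m2["P"]]) <= 2.0:
                add(m1["O3'"], m2["P"], "covalent_single")

    # (3) disulfide bridges
    sg = [i for i in atoms.index if atoms.at[i, "name"] == "SG"]
    for i, a in enumerate(sg):
        for b in sg[i + 1 :]:
            if np.linalg.norm(pos[a] - pos[b]) <= 2.5:
                add(a, b, "disulfide")

    # (4) distance fallback over heavy atoms (Cordero radii + tolerance)
    heavy = [i for i in atoms.index if atoms.at[i, "element"] != "H"]
    if heavy:
        hxyz = np.array([pos[i] for i in heavy])
        tree = cKDTree(hxyz)
        rmax = max(COVALENT_RADII.values()) * 2 + COVALENT_TOLERANCE
        for ia, ib in tree.query_pairs(rmax):
            a, b = heavy[ia], heavy[ib]
            ra = COVALENT_RADII.get(atoms.at[a, "element"], 0.77)
            rb = COVALENT_RADII.get(atoms.at[b, "element"], 0.77)
            if np.linalg.norm(pos[a] - pos[b]) <= ra + rb + COVALENT_TOLERANCE:
                add(a, b, "covalent_single")

    # (5) hydrogens attach to their nearest eligible heavy atom
    hydrogens = [i for i in atoms.index if atoms.at[i, "element"] == "H"]
    if hydrogens and heavy:
        hxyz = np.array([pos[i] for i in heavy])
        tree = cKDTree(hxyz)
        dists, nearest = tree.query(np.array([pos[i] for i in hydrogens]))
        for h, d, j in zip(hydrogens, dists, nearest):
            if d <= 1.6:
                add(h, heavy[int(j)], "covalent_single")

    bonds.sort(key=lambda b: b.key)
    return bonds


# -- hydrogen bonds ---------------------------------------------------------


def _angle(p1, p2, p3) -> float:
    """Angle at p2 in degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _mayo_distance_term(d: float, cfg: InteractionConfig) -> float:
    r = cfg.hbond_d0 / d
    return cfg.hbond_v0 * (5.0 * r**12 - 6.0 * r**10)


def _hybridization(atoms, adj, idx) -> str:
    """Crude sp2/sp3 assignment for donor/acceptor heavy atoms."""
    el = atoms.at[idx, "element"]
    if el == "O":
        # carbonyl/carboxylate oxygens are terminal with a single heavy neighbor
        heavy_nbrs = [j for j in adj[idx] if atoms.at[j, "element"] != "H"]
        h_nbrs = [j for j in adj[idx] if atoms.at[j, "element"] == "H"]
        if len(heavy_nbrs) == 1 and not h_nbrs:
            return "sp2"
        return "sp3"
    if el == "N":
        h_nbrs = [j for j in adj[idx] if atoms.at[j, "element"] == "H"]
        if len(h_nbrs) >= 3 or len(adj[idx]) >= 4:
            return "sp3"  # ammonium-like (e.g. lysine NZ)
        return "sp2"  # amide, guanidinium, ring nitrogens
    return "sp3"


def _angular_factor(theta, phi, donor_hyb, acceptor_hyb) -> float:
    """Mayo-style hybridization-dependent angular weight, in [0, 1]."""
    t = math.radians(theta)
    damp = math.exp(-((math.pi - t) ** 6))
    cos2t = math.cos(t) ** 2
    if donor_hyb == "sp2" and acceptor_hyb == "sp2":
        ang = math.cos(math.radians(phi - 120.0)) ** 2
    elif acceptor_hyb == "sp2":
        ang = math.cos(math.radians(phi - 120.0)) ** 2
    else:
        ang = math.cos(math.radians(phi - 109.5)) ** 2
    return cos2t * damp * ang


def _within_three_bonds(adj, a, b) -> bool:
    frontier = {a}
    seen = {a}
    for _ in range(3):
        nxt = set()
        for x in frontier:
            nxt |= adj[x] - seen
        if b in nxt:
            return True
        seen |= nxt
        frontier = nxt
    return False


def detect_hbonds(
    atoms: pd.DataFrame, covalent_bonds: list, config: InteractionConfig | None = None
) -> list:
    """Hydrogen bonds (Mayo-form energies) and geometric salt bridges.

    Donors are N/O/S atoms carrying a hydrogen; acceptors are oxygens,
    sulfurs, and nitrogens without attached hydrogen and at most two
    heavy neighbors.  Without any polar hydrogens present the detector
    degrades to the distance-only mode (3.5 Å gate, 4.0 Å with sulfur)
    with a warning.
    """
    cfg = config or InteractionConfig()
    xyz = coords_array(atoms)
    pos = {idx: xyz[i] for i, idx in enumerate(atoms.index)}
    adj: dict = {i: set() for i in atoms.index}
    for b in covalent_bonds:
        if b.kind in COVALENT_KINDS:
            adj[b.a].add(b.b)
            adj[b.b].add(b.a)

    polar = [i for i in atoms.index if atoms.at[i, "element"] in ("N", "O", "S")]
    donors = []  # (heavy, hydrogen)
    for i in polar:
        for j in adj[i]:
            if atoms.at[j, "element"] == "H":
                donors.append((i, j))

    best: dict = {}

    def consider(a, b, kind, energy):
        # a salt bridge supersedes any hydrogen bond on the same atom pair
        key = (min(a, b), max(a, b))
        old = best.get(key)
        if old is None:
            best[key] = (kind, energy)
        elif old[0] != "salt_bridge" and (kind == "salt_bridge" or energy < old[1]):
            best[key] = (kind, energy)

    if donors:
        acceptors = []
        for i in polar:
            el = atoms.at[i, "element"]
            has_h = any(atoms.at[j, "element"] == "H" for j in adj[i])
            heavy_deg = sum(1 for j in adj[i] if atoms.at[j, "element"] != "H")
            if el in ("O", "S") or (el == "N" and not has_h and heavy_deg <= 2):
                acceptors.append(i)
        acc_tree = cKDTree(np.array([pos[i] for i in acceptors])) if acceptors else None
        for d_atom, h_atom in donors if acc_tree is not None else []:
            neighbors = acc_tree.query_ball_point(pos[d_atom], cfg.hbond_distance_cutoff)
            for ja in neighbors:
                a_atom = acceptors[ja]
                if a_atom == d_atom or a_atom in adj[d_atom]:
                    continue
                if adj[d_atom] & adj[a_atom]:
                    continue  # 1-3 pair
                theta = _angle(pos[d_atom], pos[h_atom], pos[a_atom])
                if theta < cfg.hbond_angle_min:
                    continue
                d = float(np.linalg.norm(pos[d_atom] - pos[a_atom]))
                base_nbrs = [j for j in adj[a_atom] if atoms.at[j, "element"] != "H"]
                if base_nbrs:
                    phi = _angle(pos[h_atom], pos[a_atom], pos[base_nbrs[0]])
                    f = _angular_factor(
                        theta,
                        phi,
                        _hybridization(atoms, adj, d_atom),
                        _hybridization(atoms, adj, a_atom),
                    )
                else:
                    f = math.cos(math.radians(theta)) ** 2
                energy = _mayo_distance_term(d, cfg) * f
                if energy <= cfg.hbond_emit_threshold:
                    consider(d_atom, a_atom, "hbond", energy)
    elif polar:
        warnings.warn(
            "no polar hydrogens found; hydrogen-bond detection degrades to "
            "distance-only mode",
            stacklevel=2,
        )
        tree = cKDTree(np.array([pos[i] for i in polar])) if polar else None
        for ii, i in enumerate(polar):
            for jj in tree.query_ball_point(pos[i], cfg.fallback_hbond_cutoff_s):
                if jj <= ii:
                    continue
                j = polar[jj]
                if j in adj[i] or (adj[i] & adj[j]):
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                gate = (
                    cfg.fallback_hbond_cutoff_s
                    if "S" in (atoms.at[i, "element"], atoms.at[j, "element"])
                    else cfg.fallback_hbond_cutoff
                )
                if d > gate:
                    continue
                energy = min(_mayo_distance_term(d, cfg), 0.0)
                if energy <= cfg.hbond_emit_threshold:
                    consider(i, j, "hbond", energy)

    # salt bridges: charged-group heavy atoms within the geometric gate
    pos_atoms = [
        i for i in atoms.index
        if (atoms.at[i, "res_name"], atoms.at[i, "name"]) in CHARGED_POSITIVE
    ]
    neg_atoms = [
        i for i in atoms.index
        if (atoms.at[i, "res_name"], atoms.at[i, "name"]) in CHARGED_NEGATIVE
    ]
    for i in pos_atoms:
        for j in neg_atoms:
            if np.linalg.norm(pos[i] - pos[j]) <= cfg.salt_bridge_cutoff:
                consider(i, j, "salt_bridge", cfg.salt_bridge_energy)

    out = [
        BondRecord(a, b, kind, energy, BARS_BY_KIND[kind])
        for (a, b), (kind, energy) in sorted(best.items())
    ]
    return out


# -- hydrophobic contacts ---------------------------------------------------


def detect_hydrophobic(
    atoms: pd.DataFrame,
    covalent_bonds: list,
    mode: str = "vdw",
    config: InteractionConfig | None = None,
) -> list:
    """Hydrophobic tethers between C/S atoms not linked within 3 bonds.

    ``vdw`` mode declares a contact when the separation is at most the
    sum of van-der-Waals radii plus a slack; ``lj`` mode evaluates a
    Lennard-Jones 12-6 energy (Lorentz-Berthelot mixing) against a
    cutoff.  Energies are recorded for dilution ordering.
    """
    if mode not in ("vdw", "lj"):
        raise ValueError(f"unknown hydrophobic mode {mode!r}")
    cfg = config or InteractionConfig()
    xyz = coords_array(atoms)
    pos = {idx: xyz[i] for i, idx in enumerate(atoms.index)}
    adj: dict = {i: set() for i in atoms.index}
    for b in covalent_bonds:
        adj[b.a].add(b.b)
        adj[b.b].add(b.a)
    cand = [i for i in atoms.index if atoms.at[i, "element"] in ("C", "S")]
    if not cand:
        return []
    tree = cKDTree(np.array([pos[i] for i in cand]))
    reach = 6.0 if mode == "lj" else (2 * max(VDW_RADII.values()) + cfg.hydrophobic_slack)
    out = []
    for ia, ib in sorted(tree.query_pairs(reach)):
        a, b = cand[ia], cand[ib]
        if _within_three_bonds(adj, a, b):
            continue
        d = float(np.linalg.norm(pos[a] - pos[b]))
        ea, eb = atoms.at[a, "element"], atoms.at[b, "element"]
        if mode == "vdw":
            if d <= VDW_RADII[ea] + VDW_RADII[eb] + cfg.hydrophobic_slack:
                out.append(
                    BondRecord(a, b, "hydrophobic", cfg.hydrophobic_energy, cfg.hydrophobic_bars)
                )
        else:
            sa, epa = LJ_PARAMS[ea]
            sb, epb = LJ_PARAMS[eb]
            sigma = 0.5 * (sa + sb)
            eps = math.sqrt(epa * epb)
            energy = 4.0 * eps * ((sigma / d) ** 12 - (sigma / d) ** 6)
            if energy <= cfg.lj_cutoff:
                out.append(BondRecord(a, b, "hydrophobic", energy, cfg.hydrophobic_bars))
    return out


# -- π interactions ---------------------------------------------------------


def _rings(atoms: pd.DataFrame):
    """Aromatic rings present in the structure: (residue key, atom index list)."""
    rings = []
    for key, res_name, name_map, _ in _residue_groups(atoms):
        for ring_names in AROMATIC_RINGS.get(res_name, []):
            if all(n in name_map for n in ring_names):
                rings.append((key, [name_map[n] for n in ring_names]))
    return rings


def _ring_geometry(pos, ring_atoms):
    pts = np.array([pos[i] for i in ring_atoms])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]  # normal = direction of least extent


def _vec_angle(v1, v2) -> float:
    cosv = abs(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(min(1.0, cosv)))


def detect_pi(
    atoms: pd.DataFrame, covalent_bonds: list, config: InteractionConfig | None = None
) -> list:
    """π-stacking (centroid distance + normal angle) and π-cation contacts."""
    cfg = config or InteractionConfig()
    xyz = coords_array(atoms)
    pos = {idx: xyz[i] for i, idx in enumerate(atoms.index)}
    rings = _rings(atoms)
    geo = [(_ring_geometry(pos, r[1])) for r in rings]
    out = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i][0] == rings[j][0]:
                continue  # two rings of the same residue (e.g. tryptophan)
            ci, ni = geo[i]
            cj, nj = geo[j]
            dist = float(np.linalg.norm(ci - cj))
            if dist > cfg.pi_stack_distance:
                continue
            ang = _vec_angle(ni, nj)
            lo, hi = cfg.pi_t_angle
            if ang <= cfg.pi_stack_angle or lo <= ang <= hi:
                a = min(rings[i][1], key=lambda x: np.linalg.norm(pos[x] - cj))
                b = min(rings[j][1], key=lambda x: np.linalg.norm(pos[x] - ci))
                out.append(BondRecord(a, b, "pi_stack", cfg.pi_stack_energy, cfg.pi_bars))
    cations = [
        i for i in atoms.index
        if (atoms.at[i, "res_name"], atoms.at[i, "name"]) in PI_CATIONS
    ]
    for (rkey, ring_atoms), (centroid, normal) in zip(rings, geo):
        for c in cations:
            if atoms.at[c, "res_name"] == rkey[3] and rkey == (
                atoms.at[c, "chain"], atoms.at[c, "res_seq"], atoms.at[c, "insertion"], atoms.at[c, "res_name"]
            ):
                continue  # cation of the ring's own residue
            v = pos[c] - centroid
            dist = float(np.linalg.norm(v))
            if dist > cfg.pi_cation_distance:
                continue
            if _vec_angle(normal, v) <= cfg.pi_cation_angle:
                a = min(ring_atoms, key=lambda x: np.linalg.norm(pos[x] - pos[c]))
                out.append(BondRecord(a, c, "pi_cation", cfg.pi_cation_energy, cfg.pi_bars))
    out.sort(key=lambda b: b.key)
    return out


def build_molecular_graph(
    atoms: pd.DataFrame, config: InteractionConfig | None = None
) -> MolecularGraph:
    """Run all detectors and assemble the atom-level interaction graph."""
    cfg = config or InteractionConfig()
    covalent = detect_covalent(atoms)
    bonds = list(covalent)
    bonds += detect_hbonds(atoms, covalent, cfg)
    if cfg.hydrophobic_enabled:
        bonds += detect_hydrophobic(atoms, covalent, cfg.hydrophobic_mode, cfg)
    if cfg.pi_enabled:
        bonds += detect_pi(atoms, covalent, cfg)
    return MolecularGraph(atoms=atoms, bonds=bonds)
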