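"""PDB parsing, interaction detection, and the body-and-bar conversion."""

import math

import numpy as np
import pytest

from rigidkit.bodybar import build_body_bar_graph, phased_precover
from rigidkit.interactions import (
    InteractionConfig,
    build_molecular_graph,
    detect_covalent,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi,
)
from rigidkit.fixtures import stacked_pair_pdb, toy_molecule_pdb
from rigidkit.pdbio import ParseError, parse_pdb
from rigidkit.pebble import Multigraph, SparsityParams, play_component_game


def _record(kind, serial, name, res, seq, xyz, element):
    return (
        f"{kind:<6s}{serial:5d} {name:<4s} {res:<3s} A{seq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}\n"
    )


def _hetatm(serial, name, res, seq, xyz, element):
    return _record("HETATM", serial, name, res, seq, xyz, element)


def _atom(serial, name, res, seq, xyz, element):
    return _record("ATOM", serial, name, res, seq, xyz, element)


# -- parsing ----------------------------------------------------------------


def test_parse_helix_columns(helix_atoms):
    assert {"serial", "name", "res_name", "chain", "res_seq", "x", "y", "z",
            "element"} <= set(helix_atoms.columns)
    assert helix_atoms["element"].isin(["C", "N", "O", "H"]).all()


def test_parse_rejects_garbage():
    with pytest.raises(ParseError):
        parse_pdb("ATOM  abcde bad line\n")


def test_parse_drops_water_and_altlocs():
    text = (
        _atom(1, "N", "ALA", 1, (0, 0, 0), "N")
        + _hetatm(2, "O", "HOH", 2, (5, 5, 5), "O")
        + "ATOM      3  CA BALA A   1       1.000   0.000   0.000  0.50"
        + " 20.00           C\n"
        + "ATOM      4  CA AALA A   1       1.400   0.000   0.000  0.50"
        + " 20.00           C\n"
    )
    atoms = parse_pdb(text)
    assert len(atoms) == 2  # water gone, only altloc A kept
    assert parse_pdb(text, keep_water=True)["res_name"].tolist().count("HOH") == 1


def test_parse_first_model_only():
    text = (
        "MODEL        1\n"
        + _atom(1, "N", "ALA", 1, (0, 0, 0), "N")
        + "ENDMDL\nMODEL        2\n"
        + _atom(1, "N", "ALA", 1, (9, 9, 9), "N")
        + "ENDMDL\n"
    )
    atoms = parse_pdb(text)
    assert len(atoms) == 1
    assert atoms.iloc[0]["x"] == 0.0


# -- covalent detection -----------------------------------------------------


def test_helix_covalent_counts(helix_mol):
    cov = helix_mol.covalent_bonds()
    # per residue: N-CA, CA-C, C-O, CA-CB, N-H = 5 bonds; 9 peptide links
    assert len(cov) == 10 * 5 + 9
    peptide = [b for b in cov if b.kind == "peptide"]
    assert len(peptide) == 9
    assert all(b.bars == 6 for b in peptide)
    singles = [b for b in cov if b.kind == "covalent_single"]
    assert all(b.bars == 5 for b in singles)


def test_double_bond_from_template():
    mol_double = parse_pdb(toy_molecule_pdb("double_bond"))
    bonds = detect_covalent(mol_double)
    cc = [b for b in bonds if b.kind.startswith("covalent") and b.bars == 6]
    assert len(cc) == 1


def test_disulfide_bridge():
    text = (
        _atom(1, "SG", "CYS", 1, (0.0, 0.0, 0.0), "S")
        + _atom(2, "SG", "CYS", 2, (2.04, 0.0, 0.0), "S")
    )
    bonds = detect_covalent(parse_pdb(text))
    ss = [b for b in bonds if b.kind == "disulfide"]
    assert len(ss) == 1
    assert ss[0].bars == 5


def test_distance_fallback_for_unknown_residue():
    text = (
        _hetatm(1, "C1", "LIG", 1, (0.0, 0.0, 0.0), "C")
        + _hetatm(2, "C2", "LIG", 1, (1.54, 0.0, 0.0), "C")
        + _hetatm(3, "C3", "LIG", 1, (8.0, 0.0, 0.0), "C")
    )
    bonds = detect_covalent(parse_pdb(text))
    assert len(bonds) == 1  # only the 1.54 Å pair


# -- hydrogen bonds ---------------------------------------------------------


def _hbond_geometry(d_da, theta_deg=180.0):
    """Donor N-H pointing at a carbonyl O with donor-acceptor distance d_da."""
    u = np.array([0.5, math.sqrt(3) / 2, 0.0])  # 120 deg off the C=O axis
    lines = (
        _hetatm(1, "C", "LIG", 1, (-1.23, 0.0, 0.0), "C")
        + _hetatm(2, "O", "LIG", 1, (0.0, 0.0, 0.0), "O")
        + _hetatm(3, "C2", "LIG", 1, (-1.87, 1.23, 0.0), "C")
    )
    n = u * d_da
    if theta_deg == 180.0:
        h = u * (d_da - 1.0)
    else:
        # rotate the N-H direction away from collinear in-plane
        phi = math.radians(180.0 - theta_deg)
        axis = np.array([-u[1], u[0], 0.0])
        h = n - (math.cos(phi) * u - math.sin(phi) * axis) * 1.0
    lines += _hetatm(4, "N", "AMN", 2, tuple(n), "N")
    lines += _hetatm(5, "H", "AMN", 2, tuple(h), "H")
    lines += _hetatm(6, "C", "AMN", 2, tuple(n + np.array([0.0, 0.0, 1.47])), "C")
    return parse_pdb(lines)


def _hbond_energies(atoms):
    cov = detect_covalent(atoms)
    return [b.energy for b in detect_hbonds(atoms, cov) if b.kind == "hbond"]


def test_mayo_energy_at_equilibrium_distance():
    energies = _hbond_energies(_hbond_geometry(2.8))
    assert len(energies) == 1
    # distance term is exactly -V0 at d0; angular factor is near 1 here
    assert -8.0 <= energies[0] <= -7.0


def test_mayo_energy_weakens_with_distance():
    near = _hbond_energies(_hbond_geometry(2.8))[0]
    far = _hbond_energies(_hbond_geometry(3.5))[0]
    assert near < far < 0.0


def test_hbond_angle_gate():
    assert _hbond_energies(_hbond_geometry(2.8, theta_deg=95.0)) == []


def test_hbond_distance_gate():
    assert _hbond_energies(_hbond_geometry(5.0)) == []


def test_helix_has_i_i4_hbonds(helix_mol):
    hb = [b for b in helix_mol.bonds if b.kind == "hbond"]
    atoms = helix_mol.atoms
    spans = set()
    for b in hb:
        spans.add(abs(int(atoms.at[b.a, "res_seq"]) - int(atoms.at[b.b, "res_seq"])))
    assert 4 in spans
    strong = [b for b in hb if b.energy < -1.0]
    assert len(strong) == 6  # donors N(5..10) to acceptors O(1..6)


def test_distance_only_fallback_warns():
    text = (
        _hetatm(1, "O1", "LIG", 1, (0.0, 0.0, 0.0), "O")
        + _hetatm(2, "O2", "LIG", 2, (3.2, 0.0, 0.0), "O")
    )
    atoms = parse_pdb(text)
    with pytest.warns(UserWarning, match="distance-only"):
        bonds = detect_hbonds(atoms, [])
    assert len(bonds) == 1
    # at 3.6 Å the O-O pair is outside the 3.5 Å fallback gate
    text2 = text.replace("   3.200", "   3.600")
    with pytest.warns(UserWarning):
        assert detect_hbonds(parse_pdb(text2), []) == []


def test_fallback_sulfur_gate_is_wider():
    text = (
        _hetatm(1, "SD", "LIG", 1, (0.0, 0.0, 0.0), "S")
        + _hetatm(2, "O1", "LIG", 2, (3.8, 0.0, 0.0), "O")
    )
    with pytest.warns(UserWarning):
        bonds = detect_hbonds(parse_pdb(text), [])
    assert len(bonds) == 1


def test_salt_bridge_detection_and_energy():
    text = (
        _atom(1, "NZ", "LYS", 1, (0.0, 0.0, 0.0), "N")
        + _atom(2, "HZ1", "LYS", 1, (-1.0, 0.0, 0.0), "H")
        + _atom(3, "OE1", "GLU", 2, (3.5, 0.0, 0.0), "O")
    )
    atoms = parse_pdb(text)
    bonds = detect_hbonds(atoms, detect_covalent(atoms))
    sb = [b for b in bonds if b.kind == "salt_bridge"]
    assert len(sb) == 1
    assert sb[0].energy == -10.0
    assert sb[0].bars == 5
    # a salt bridge supersedes a plain hydrogen bond on the same pair
    assert len([b for b in bonds if b.key == sb[0].key]) == 1


# -- hydrophobic tethers ----------------------------------------------------


def _carbon_pair(d):
    text = (
        _hetatm(1, "C1", "LIG", 1, (0.0, 0.0, 0.0), "C")
        + _hetatm(2, "C2", "LIG", 2, (d, 0.0, 0.0), "C")
    )
    return parse_pdb(text)


def test_hydrophobic_vdw_gate():
    # gate = r_vdw(C) + r_vdw(C) + 0.25 = 3.65 Å
    assert len(detect_hydrophobic(_carbon_pair(3.5), [], mode="vdw")) == 1
    assert detect_hydrophobic(_carbon_pair(3.8), [], mode="vdw") == []
    bond = detect_hydrophobic(_carbon_pair(3.5), [], mode="vdw")[0]
    assert bond.bars == 3
    assert bond.energy == -0.5


def test_hydrophobic_lj_mode():
    # at the sigma crossing the LJ energy is 0 and fails the -0.05 gate;
    # at the minimum (2^(1/6) sigma = 3.82 Å) it is -epsilon = -0.11
    assert detect_hydrophobic(_carbon_pair(3.40), [], mode="lj") == []
    bonds = detect_hydrophobic(_carbon_pair(3.82), [], mode="lj")
    assert len(bonds) == 1
    assert bonds[0].energy == pytest.approx(-0.11, abs=0.01)


def test_hydrophobic_excludes_close_covalent_relatives():
    atoms = parse_pdb(toy_molecule_pdb("branched"))
    cov = detect_covalent(atoms)
    # all heavy atoms are within three covalent bonds of each other
    assert detect_hydrophobic(atoms, cov, mode="vdw") == []


# -- pi systems -------------------------------------------------------------


def test_pi_stacking_on_ring_pair():
    atoms = parse_pdb(stacked_pair_pdb())
    cov = detect_covalent(atoms)
    bonds = detect_pi(atoms, cov)
    stack = [b for b in bonds if b.kind == "pi_stack"]
    assert len(stack) >= 1
    assert all(b.bars == 3 for b in stack)


def test_pi_stacking_gone_when_far():
    atoms = parse_pdb(stacked_pair_pdb(separation=7.0))
    cov = detect_covalent(atoms)
    assert [b for b in detect_pi(atoms, cov) if b.kind == "pi_stack"] == []


# -- body-and-bar -----------------------------------------------------------


def test_single_bond_toy_body_bar(toy_mol):
    bbg = build_body_bar_graph(toy_mol("single_bond"))
    assert len(bbg.bodies) == 2
    assert list(bbg.bar_weight.values()) == [5]


def test_double_bond_toy_body_bar(toy_mol):
    bbg = build_body_bar_graph(toy_mol("double_bond"))
    assert list(bbg.bar_weight.values()) == [6]


def test_branched_toy_bodies(toy_mol):
    bbg = build_body_bar_graph(toy_mol("branched"))
    assert len(bbg.bodies) == 5


def test_bar_weight_capped_at_six(helix_mol):
    bbg = build_body_bar_graph(helix_mol)
    assert max(bbg.bar_weight.values()) <= 6


def test_phased_precover_matches_cold_start(helix_mol):
    params = SparsityParams(6, 6)
    bbg = build_body_bar_graph(helix_mol)
    g, queue = phased_precover(bbg, params)
    g.audit()
    for q in queue:
        for _ in range(q.count):
            g.try_insert_edge(q.u, q.v)
    g.audit()
    cold = Multigraph.from_edges(
        [(u, v, w) for (u, v), w in sorted(bbg.bar_weight.items())],
        vertices=sorted(bbg.bodies),
    )
    summary, cold_comps = play_component_game(cold, params)
    assert g.accepted_multigraph().n_edges == summary.accepted_count
    dump = g.state_dump()
    assert sum(dump["pebbles"].values()) == summary.free_pebbles
    # same rank implies the same closure, hence identical component families
    _, phased_comps = play_component_game(g.accepted_multigraph(), params)
    fam = lambda comps: sorted(sorted(c.vertex_ids) for c in comps)
    assert fam(phased_comps) == fam(cold_comps)
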