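"""Per-frame trajectory analysis and frame iteration."""

import numpy as np
import pytest

from rigidkit.fixtures import ideal_helix_pdb
from rigidkit.pdbio import coords_array, parse_pdb
from rigidkit.trajectory import analyze_trajectory, iter_frames, read_multimodel_frames

HELIX = ideal_helix_pdb(6)
ATOMS = parse_pdb(HELIX)
BASE = coords_array(ATOMS)


def _multimodel(frames):
    atom_lines = [l for l in HELIX.splitlines() if l.startswith(("ATOM", "HETATM"))]
    out = []
    for i, coords in enumerate(frames, start=1):
        out.append(f"MODEL     {i:4d}")
        for line, (x, y, z) in zip(atom_lines, coords):
            out.append(line[:30] + f"{x:8.3f}{y:8.3f}{z:8.3f}" + line[54:])
        out.append("ENDMDL")
    return "\n".join(out) + "\nEND\n"


def _broken():
    coords = BASE.copy()
    idx = ATOMS.index.get_indexer(ATOMS.index[ATOMS["res_seq"] > 3])
    coords[idx] += np.array([25.0, 0.0, 0.0])
    return coords


def test_read_multimodel_frames_roundtrip():
    frames = read_multimodel_frames(_multimodel([BASE, _broken()]))
    assert len(frames) == 2
    assert np.allclose(frames[0], BASE, atol=1e-3)


def test_single_model_pdb_is_one_frame():
    frames = read_multimodel_frames(HELIX)
    assert len(frames) == 1


def test_identical_frames_identical_results():
    results = analyze_trajectory(HELIX, [BASE, BASE.copy()])
    fam = lambda fr: sorted(sorted(c.atom_refs) for c in fr.components)
    assert fam(results[0]) == fam(results[1])
    assert results[0].colors == results[1].colors


def test_perturbed_frame_loses_rigidity():
    results = analyze_trajectory(HELIX, [BASE, _broken(), BASE.copy()])
    n0 = max(len(c.atom_refs) for c in results[0].components)
    n1 = max(len(c.atom_refs) for c in results[1].components)
    assert n1 < n0
    assert len(results[1].components) > len(results[0].components)
    # the recovered frame matches the first one
    fam = lambda fr: sorted(sorted(c.atom_refs) for c in fr.components)
    assert fam(results[2]) == fam(results[0])


def test_stride_selects_every_nth_frame():
    frames = [BASE, _broken(), BASE.copy(), _broken()]
    indices = [i for i, _, _ in iter_frames(HELIX, frames, stride=2)]
    assert indices == [0, 2]
    results = analyze_trajectory(HELIX, frames, stride=3)
    assert [r.frame_index for r in results] == [0, 3]


def test_atom_count_mismatch_raises():
    with pytest.raises(ValueError, match="frame 0"):
        list(iter_frames(HELIX, [BASE[:-1]]))


def test_bad_stride_raises():
    with pytest.raises(ValueError):
        list(iter_frames(HELIX, [BASE], stride=0))


def test_multimodel_text_input():
    results = analyze_trajectory(HELIX, _multimodel([BASE, _broken()]))
    assert len(results) == 2
    assert len(results[1].components) > len(results[0].components)


def test_colors_thread_across_frames():
    results = analyze_trajectory(HELIX, [BASE, BASE.copy(), _broken()])
    assert results[0].colors[0] == results[1].colors[0]
    # the broken frame's colors are all defined and distinct per component
    cols = list(results[2].colors.values())
    assert len(cols) == len(set(cols))
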