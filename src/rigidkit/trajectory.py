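"""Per-frame rigidity analysis over a coordinate time series.

Covalent bonds are chemistry, not geometry: they are detected once on
the topology structure and held fixed.  Non-covalent interactions are
re-evaluated on every frame's coordinates, the (6,6) component game is
replayed (no dilution), and components are tracked across frames with
consistent coloring.  Each frame's result is a pure function of
(topology, frame coordinates, config); only the coloring threads state
between frames.

The native coordinate-series format is a multi-model PDB (one MODEL per
frame).  Binary trajectory formats (XTC and friends) are supported
through an optional MDAnalysis adapter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactions import (
    InteractionConfig,
    MolecularGraph,
    detect_covalent,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi,
)
from .pdbio import parse_pdb
from .pipeline import consistent_colors, run_rigidity

__all__ = ["FrameResult", "iter_frames", "analyze_trajectory", "read_multimodel_frames"]


@dataclass
class FrameResult:
    frame_index: int
    time: float | None          # ps, when the source provides it
    components: list            # AtomComponents
    colors: dict                # component position -> color id


def read_multimodel_frames(text: str) -> list:
    """Coordinate sets of every MODEL block in a multi-model PDB.

    Returns a list of (n_atoms, 3) arrays in model order.  A file
    without MODEL records yields a single frame.
    """
    frames: list = []
    current: list | None = None
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            if current:
                frames.append(np.array(current))
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model:
                    continue
                current = []
                frames.append(None)  # placeholder for the single implicit model
            current.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if frames and frames[0] is None:
        frames[0] = np.array(current)
    return [f for f in frames if f is not None and len(f)]


def _xtc_frames(topology_pdb: str, path: str):
    """Optional adapter: frames (coords in Å, time in ps) from XTC via MDAnalysis."""
    import tempfile

    import MDAnalysis as mda

    with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
        fh.write(topology_pdb)
        fh.flush()
        u = mda.Universe(fh.name, path)
        for ts in u.trajectory:
            yield np.array(ts.positions, dtype=float), float(ts.time)


def iter_frames(topology_pdb: str, coordinate_series, stride: int = 1):
    """Yield (frame_index, coords, time) at indices 0, stride, 2*stride, ...

    ``coordinate_series`` may be multi-model PDB text, a path to an XTC
    file, or an iterable of (n_atoms, 3) arrays.  Every frame must match
    the topology atom count.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    n_atoms = len(parse_pdb(topology_pdb))
    if isinstance(coordinate_series, str) and coordinate_series.endswith(".xtc"):
        source = _xtc_frames(topology_pdb, coordinate_series)
    elif isinstance(coordinate_series, str):
        source = ((c, None) for c in read_multimodel_frames(coordinate_series))
    else:
        source = (
            (np.asarray(c, float), None) if not isinstance(c, tuple) else c
            for c in coordinate_series
        )
    for i, (coords, time) in enumerate(source):
        if i % stride:
            continue
        if len(coords) != n_atoms:
            raise ValueError(
                f"frame {i}: {len(coords)} atoms but topology has {n_atoms}"
            )
        yield i, coords, time


def _frame_molecular_graph(atoms: pd.DataFrame, covalent: list, coords, cfg):
    frame_atoms = atoms.copy()
    frame_atoms[["x", "y", "z"]] = np.asarray(coords, float)
    bonds = list(covalent)
    bonds += detect_hbonds(frame_atoms, covalent, cfg)
    if cfg.hydrophobic_enabled:
        bonds += detect_hydrophobic(frame_atoms, covalent, cfg.hydrophobic_mode, cfg)
    if cfg.pi_enabled:
        bonds += detect_pi(frame_atoms, covalent, cfg)
    return MolecularGraph(atoms=frame_atoms, bonds=bonds)


def analyze_trajectory(
    topology_pdb: str,
    frames,
    config: InteractionConfig | None = None,
    stride: int = 1,
) -> list:
    """Rigid components per frame, with colors threaded across frames.

    ``frames`` is anything :func:`iter_frames` accepts.  Covalent bonds
    come from the topology once; each frame re-runs the non-covalent
    detectors and the component game independently, so frame evaluation
    is stateless and order-insensitive (the coloring pass is applied
    afterwards in frame order).
    """
    cfg = config or InteractionConfig()
    atoms = parse_pdb(topology_pdb)
    covalent = detect_covalent(atoms)
    raw: list = []
    for idx, coords, time in iter_frames(topology_pdb, frames, stride):
        mol = _frame_molecular_graph(atoms, covalent, coords, cfg)
        components, _ = run_rigidity(mol, cfg)
        raw.append((idx, time, components))
    colors = consistent_colors([comps for _, _, comps in raw])
    results = []
    for t, (idx, time, components) in enumerate(raw):
        frame_colors = {
            i: colors[(t, frozenset(c.atom_refs))] for i, c in enumerate(components)
        }
        results.append(
            FrameResult(frame_index=idx, time=time, components=components, colors=frame_colors)
        )
    return results
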