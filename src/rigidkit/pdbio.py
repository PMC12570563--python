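"""Fixed-column PDB text parsing into a pandas atom table.

Only the coordinate section is consumed (ATOM/HETATM/MODEL/ENDMDL/TER/
END).  The atom table is a plain DataFrame with one row per atom and the
columns of the classic PDB record: serial, name, alt_loc, res_name,
chain, res_seq, insertion, x/y/z (Å), occupancy, element, is_hetero.
Rules: first MODEL only, alternate locations filtered to blank/'A',
waters dropped unless requested.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .templates import WATER_NAMES

__all__ = ["parse_pdb", "ParseError", "coords_array", "residue_key"]

# two-letter element symbols we recognize when inferring from the name column
_TWO_LETTER = {
    "CL", "BR", "FE", "ZN", "MG", "NA", "SE", "MN", "CU", "NI", "CO", "CD",
}

_COLUMNS = [
    "serial", "name", "alt_loc", "res_name", "chain", "res_seq",
    "insertion", "x", "y", "z", "occupancy", "element", "is_hetero",
]


class ParseError(ValueError):
    """Malformed mandatory column in a coordinate record."""


def _infer_element(name: str, res_name: str) -> str:
    """Infer the element from the atom-name column when col 77-78 is blank."""
    raw = name.strip()
    if not raw:
        return ""
    if raw[0].isdigit():  # e.g. 1HB2
        return "H"
    alpha = "".join(c for c in raw if c.isalpha()).upper()
    if not alpha:
        return ""
    if alpha[:2] in _TWO_LETTER and len(name) >= 2 and name[0] != " ":
        return alpha[:2]
    if alpha[0] == "H":
        return "H"
    return alpha[0]


def parse_pdb(text: str, keep_water: bool = False) -> pd.DataFrame:
    """Parse PDB text into an atom table.

    Only the first MODEL is read.  Alternate locations other than
    blank/'A' are discarded.  Raises :class:`ParseError` (with the line
    number) when a mandatory column does not parse, or when no atom
    records are present.
    """
    rows = []
    in_first_model = True
    model_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if model_seen:
                in_first_model = False
            model_seen = True
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if rec not in ("ATOM", "HETATM") or not in_first_model:
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            alt_loc = line[16].strip() if len(line) > 16 else ""
            res_name = line[17:20].strip()
            chain = line[21] if len(line) > 21 else " "
            res_seq = int(line[22:26])
            insertion = line[26].strip() if len(line) > 26 else ""
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed coordinate record: {exc}") from exc
        try:
            occupancy = float(line[54:60])
        except (ValueError, IndexError):
            occupancy = 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(line[12:16], res_name)
        if not element:
            raise ParseError(f"line {lineno}: cannot determine element for atom {name!r}")
        if not all(math.isfinite(c) for c in (x, y, z)):
            raise ParseError(f"line {lineno}: non-finite coordinates")
        if alt_loc not in ("", "A"):
            continue
        if not keep_water and res_name in WATER_NAMES:
            continue
        rows.append(
            (serial, name, alt_loc, res_name, chain, res_seq, insertion,
             x, y, z, occupancy, element, rec == "HETATM")
        )
    if not rows:
        raise ParseError("no ATOM/HETATM records found")
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.index.name = "atom_index"
    return df


def coords_array(atoms: pd.DataFrame) -> np.ndarray:
    """The (n_atoms, 3) coordinate block as a float array."""
    return atoms[["x", "y", "z"]].to_numpy(float)


def residue_key(row) -> tuple:
    """(chain, res_seq, insertion) identifying the residue of an atom row."""
    return (row.chain, int(row.res_seq), row.insertion)
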