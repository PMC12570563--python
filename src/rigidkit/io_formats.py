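"""Readers and writers: GraphML input, results XML, residue JSON, PyMOL scripts.

The results document is a small XML dialect (schema shipped with the
package) holding the game parameters, the classification, the component
membership lists and — for molecular runs — the dilution steps with
their energies.  All writers are deterministic: stable ordering, no
timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
from lxml import etree

from .pebble import Multigraph

__all__ = [
    "ResultsDocument",
    "read_graphml",
    "write_results_xml",
    "read_results_xml",
    "write_residue_json",
    "write_pymol_script",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed or schema-invalid input document."""


def read_graphml(text: str) -> Multigraph:
    """Parse a GraphML document into a multigraph.

    Edges are treated as undirected; repeated edges accumulate
    multiplicity, and an integer edge attribute ``weight`` is read as a
    multiplicity (the molecular bar convention).  Other attributes are
    ignored.
    """
    try:
        g = nx.parse_graphml(text, force_multigraph=True)
    except Exception as exc:
        raise FormatError(f"invalid GraphML: {exc}") from exc
    edges = []
    for u, v, data in g.edges(data=True):
        w = data.get("weight", 1)
        try:
            mult = int(w)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-integer edge weight {w!r}") from exc
        if mult < 1:
            raise FormatError(f"edge weight must be positive, got {mult}")
        edges.append((u, v, mult))
    return Multigraph.from_edges(edges, vertices=list(g.nodes))


# -- results XML ------------------------------------------------------------


@dataclass
class ResultsDocument:
    """In-memory form of a rigidity-results file."""

    k: int
    l: int
    category: str
    nodes: list                      # node/atom identifiers (strings)
    components: list                 # list of sorted member-id lists
    input_id: str | None = None
    dilution: list = field(default_factory=list)  # (index, energy, components)


def _schema() -> etree.XMLSchema:
    with resources.files("rigidkit.data").joinpath("results.xsd").open("rb") as fh:
        return etree.XMLSchema(etree.parse(fh))


def _components_el(parent, components):
    comps_el = etree.SubElement(parent, "components")
    for comp in sorted(components, key=lambda c: (-len(c), c)):
        comp_el = etree.SubElement(comps_el, "component")
        for member in sorted(comp):
            etree.SubElement(comp_el, "member", id=str(member))


def write_results_xml(doc: ResultsDocument) -> str:
    root = etree.Element("rigidity-result")
    etree.SubElement(root, "params", k=str(doc.k), l=str(doc.l))
    if doc.input_id is not None:
        etree.SubElement(root, "input", id=doc.input_id)
    etree.SubElement(root, "category").text = doc.category
    nodes_el = etree.SubElement(root, "nodes")
    for node in sorted(doc.nodes):
        etree.SubElement(nodes_el, "node", id=str(node))
    _components_el(root, doc.components)
    if doc.dilution:
        dil_el = etree.SubElement(root, "dilution")
        for index, energy, comps in doc.dilution:
            step_el = etree.SubElement(
                dil_el, "step", index=str(index), energy=repr(float(energy))
            )
            _components_el(step_el, comps)
    _schema().assertValid(root)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _read_components(parent) -> list:
    comps = []
    comps_el = parent.find("components")
    for comp_el in comps_el.findall("component"):
        comps.append(sorted(m.get("id") for m in comp_el.findall("member")))
    return comps


def read_results_xml(text: str) -> ResultsDocument:
    """Inverse of :func:`write_results_xml`; validates schema and references."""
    try:
        root = etree.fromstring(text.encode())
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"invalid XML: {exc}") from exc
    schema = _schema()
    if not schema.validate(root):
        raise FormatError(f"schema violation: {schema.error_log.last_error}")
    params = root.find("params")
    nodes = sorted(n.get("id") for n in root.find("nodes").findall("node"))
    node_set = set(nodes)
    components = _read_components(root)
    for comp in components:
        for member in comp:
            if member not in node_set:
                raise FormatError(f"component references unknown node {member!r}")
    dilution = []
    dil_el = root.find("dilution")
    if dil_el is not None:
        for step_el in dil_el.findall("step"):
            comps = _read_components(step_el)
            for comp in comps:
                for member in comp:
                    if member not in node_set:
                        raise FormatError(
                            f"dilution step references unknown node {member!r}"
                        )
            dilution.append(
                (int(step_el.get("index")), float(step_el.get("energy")), comps)
            )
    input_el = root.find("input")
    return ResultsDocument(
        k=int(params.get("k")),
        l=int(params.get("l")),
        category=root.findtext("category"),
        nodes=nodes,
        components=sorted(components, key=lambda c: (-len(c), c)),
        input_id=None if input_el is None else input_el.get("id"),
        dilution=dilution,
    )


# -- residue JSON -----------------------------------------------------------


def write_residue_json(residue_components: list) -> str:
    """Residue-level components as a JSON document with stable ordering.

    Input: list of lists of (chain, res_seq, insertion) tuples, as
    produced by the pipeline's residue mapping.
    """
    payload = []
    for comp in sorted(residue_components, key=lambda c: (-len(c), sorted(c))):
        payload.append(
            {
                "size": len(comp),
                "residues": [
                    {"chain": c, "res_seq": s, "insertion": i}
                    for c, s, i in sorted(comp)
                ],
            }
        )
    return json.dumps(payload, indent=2) + "\n"


# -- PyMOL ------------------------------------------------------------------

# fixed palette cycled deterministically over component colors
_PALETTE = [
    "red", "blue", "green", "yellow", "orange", "magenta", "cyan", "salmon",
    "purple", "teal", "olive", "wheat", "hotpink", "slate", "limegreen", "chocolate",
]


def write_pymol_script(components: list, colors: dict | None, structure_id: str) -> str:
    """Selection + color commands for each non-trivial component.

    ``components`` is a list of atom-serial lists; ``colors`` maps the
    component position to a color id (defaults to the position itself).
    """
    lines = [
        f"# rigid components of {structure_id}",
        "bg_color white",
        "hide everything",
        "show sticks",
        "color grey80",
    ]
    for i, comp in enumerate(components):
        if len(comp) < 2:
            continue
        color_id = colors.get(i, i) if colors else i
        sel = "+".join(str(s) for s in sorted(comp))
        name = f"comp{i + 1:03d}"
        lines.append(f"select {name}, {structure_id} and id {sel}")
        lines.append(f"color {_PALETTE[color_id % len(_PALETTE)]}, {name}")
    lines.append("deselect")
    return "\n".join(lines) + "\n"
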