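"""SD-file input, potency parsing, and all output artifacts.

Input is restricted to SD files (V2000/V3000): potency values are read from
configurable SD property tags and are expected on a negative-log scale
(pKi / pIC50). Writers are deterministic: identical inputs produce
byte-identical outputs, which makes reports and graph exports directly
diffable across runs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdDepictor

logger = logging.getLogger(__name__)

GRAPH_FORMATS = ("graphml", "dot", "json")

_JSON_SCHEMA = "analogsar-graph/1"


@dataclass
class PotencyConfig:
    """Which SD property tags hold potency values, and their target names.

    ``field_names`` and ``target_labels`` are parallel lists; a selectivity
    analysis needs at least two fields.
    """

    field_names: Sequence[str]
    target_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not self.field_names:
            raise ValueError("PotencyConfig needs at least one potency field")
        if self.target_labels is None:
            self.target_labels = list(self.field_names)
        if len(self.target_labels) != len(self.field_names):
            raise ValueError("field_names and target_labels must have equal length")


@dataclass
class CompoundRecord:
    """One molecule: identifier, structure (with stereo), potency map."""

    compound_id: str
    mol: Chem.Mol
    potencies: dict[str, float] = field(default_factory=dict)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count (salt stripping).

    Ties are broken by the lexicographically smallest canonical SMILES so the
    choice never depends on fragment order in the input record.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), _neg_smiles(f)))
    return best


class _neg_smiles(str):
    """Reverse-order string wrapper: max() picks the smallest SMILES."""

    def __new__(cls, mol: Chem.Mol):
        return super().__new__(cls, Chem.MolToSmiles(mol))

    def __lt__(self, other):  # invert comparisons
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def read_sd_file(path: str | Path, config: PotencyConfig) -> list[CompoundRecord]:
    """Read an SD file into compound records.

    One record per parsable molecule block, in file order. Multi-fragment
    entries are reduced to their largest fragment; molecules missing every
    configured potency field are dropped with a warning; unparsable blocks
    are skipped with a warning. An unreadable file raises ``OSError``.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read SD file: {path}")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    records: list[CompoundRecord] = []
    seen_ids: set[str] = set()
    seen_structures: dict[str, str] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("%s: molecule block %d is unparsable, skipped", path.name, i + 1)
            continue
        potencies: dict[str, float] = {}
        for fname, label in zip(config.field_names, config.target_labels):
            if mol.HasProp(fname):
                try:
                    value = float(mol.GetProp(fname))
                except ValueError:
                    continue
                if math.isfinite(value):
                    potencies[label] = value
        if not potencies:
            logger.warning(
                "%s: molecule block %d lacks every potency field %s, dropped",
                path.name, i + 1, list(config.field_names),
            )
            continue
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        stripped = _largest_fragment(mol)
        for k, v in props.items():
            stripped.SetProp(k, v)
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name").strip() else f"MOL{i + 1}"
        if cid in seen_ids:
            new_cid = f"{cid}#{i + 1}"
            logger.warning("duplicate compound_id %r renamed to %r", cid, new_cid)
            cid = new_cid
        seen_ids.add(cid)
        Chem.AssignStereochemistry(stripped, cleanIt=True, force=True)
        smi = Chem.MolToSmiles(stripped)
        if smi in seen_structures:
            logger.info("compound %s duplicates structure of %s", cid, seen_structures[smi])
        else:
            seen_structures[smi] = cid
        records.append(CompoundRecord(compound_id=cid, mol=stripped, potencies=potencies))
    return records


def write_sd_file(records: Iterable[CompoundRecord], path: str | Path,
                  potency_fields: Mapping[str, str] | None = None) -> None:
    """Write records back to SDF with potency tags.

    ``potency_fields`` maps target label -> SD tag name; by default the
    label itself is used as the tag.
    """
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.Mol(rec.mol)
            if mol.GetNumConformers() == 0:
                rdDepictor.Compute2DCoords(mol)
            mol.SetProp("_Name", rec.compound_id)
            for label, value in rec.potencies.items():
                tag = potency_fields.get(label, label) if potency_fields else label
                mol.SetProp(tag, str(value))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# subset report


def write_subset_report(partition, series_id: str, path: str | Path, *,
                        assignments: Mapping[str, object],
                        potencies: Mapping[str, Mapping[str, float]],
                        stereo_indices: Mapping[str, int] | None = None) -> None:
    """Write the tab-separated per-subset compound report.

    One row per compound: series id, subset label, compound id, the R-group
    at each indexed site (SMILES with a ``*`` attachment marker, ``H`` when
    unsubstituted), every potency, and the stereo-group index when the
    compound belongs to a stereoisomer group. Rows are ordered by subset
    (layer, then site combination) then compound id; output bytes are a pure
    function of the inputs.
    """
    stereo_indices = stereo_indices or {}
    n_sites = 0
    for a in assignments.values():
        n_sites = max(n_sites, max(a.groups, default=0))
    targets = sorted({t for p in potencies.values() for t in p})
    header = ["series_id", "subset", "compound_id"]
    header += [f"R{i}" for i in range(1, n_sites + 1)]
    header += targets
    header.append("stereo_group")
    lines = ["\t".join(header)]
    combos = sorted(partition.subsets, key=lambda c: (len(c.sites), tuple(sorted(c.sites))))
    for combo in combos:
        for cid in sorted(partition.subsets[combo]):
            a = assignments[cid]
            row = [series_id, combo.label, cid]
            row += [a.groups.get(i, "H") for i in range(1, n_sites + 1)]
            row += [f"{potencies[cid][t]:.2f}" if t in potencies.get(cid, {}) else "" for t in targets]
            idx = stereo_indices.get(cid)
            row.append(str(idx) if idx is not None else "")
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# graph export


def _as_networkx(graph) -> nx.DiGraph:
    if isinstance(graph, nx.DiGraph):
        return graph
    if hasattr(graph, "to_networkx"):
        return graph.to_networkx()
    raise TypeError(f"cannot export object of type {type(graph).__name__} as a graph")


def _clean_attrs(attrs: Mapping[str, object]) -> dict:
    """Drop undefined (None) attributes, coerce the rest to primitives."""
    out = {}
    for k in sorted(attrs):
        v = attrs[k]
        if v is None:
            continue
        if isinstance(v, (bool, int, float, str)):
            out[k] = v
        elif isinstance(v, (tuple, list, frozenset, set)):
            out[k] = ",".join(str(x) for x in sorted(v))
        else:
            out[k] = str(v)
    return out


def export_graph(graph, format: str, path: str | Path) -> None:
    """Export a SAR graph or R-group tree to graphml, dot, or json.

    Node attributes (label, count, mean potency, potency range, empty flag,
    layer, stereo index) ride along; the json form round-trips exactly via
    :func:`import_graph_json`.
    """
    if format not in GRAPH_FORMATS:
        raise ValueError(f"unknown graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}")
    g = _as_networkx(graph)
    path = Path(path)
    if format == "json":
        payload = {
            "schema": _JSON_SCHEMA,
            "graph": _clean_attrs(g.graph),
            "nodes": [dict(id=n, **_clean_attrs(g.nodes[n])) for n in sorted(g.nodes)],
            "edges": [{"source": u, "target": v} for u, v in sorted(g.edges)],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif format == "dot":
        path.write_text(_to_dot(g))
    elif format == "graphml":
        ordered = nx.DiGraph(**_clean_attrs(g.graph))
        for n in sorted(g.nodes):
            ordered.add_node(n, **_clean_attrs(g.nodes[n]))
        ordered.add_edges_from(sorted(g.edges))
        nx.write_graphml(ordered, str(path), named_key_ids=True)


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _to_dot(g: nx.DiGraph) -> str:
    lines = ["digraph sar {"]
    for n in sorted(g.nodes):
        attrs = _clean_attrs(g.nodes[n])
        label = attrs.get("label", n)
        extra = " ".join(f"{k}={_dot_quote(v)}" for k, v in attrs.items() if k != "label")
        lines.append(f"  {_dot_quote(n)} [label={_dot_quote(label)}{(' ' + extra) if extra else ''}];")
    for u, v in sorted(g.edges):
        lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def import_graph_json(path: str | Path) -> nx.DiGraph:
    """Parse a json graph export back into a DiGraph (round-trip inverse)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _JSON_SCHEMA:
        raise ValueError(f"not an analogsar graph json file: {path}")
    g = nx.DiGraph(**payload.get("graph", {}))
    for node in payload["nodes"]:
        node = dict(node)
        nid = node.pop("id")
        g.add_node(nid, **node)
    for e in payload["edges"]:
        g.add_edge(e["source"], e["target"])
    return g


def graphs_equal(a, b) -> bool:
    """Node set, edge set, and exported attributes all equal."""
    ga, gb = _as_networkx(a), _as_networkx(b)
    if set(ga.nodes) != set(gb.nodes) or set(ga.edges) != set(gb.edges):
        return False
    return all(_clean_attrs(ga.nodes[n]) == _clean_attrs(gb.nodes[n]) for n in ga.nodes)
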