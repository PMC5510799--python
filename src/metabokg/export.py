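"""Bulk serialization for property-graph batch importers, plus query-result
writers.

The bulk dialect follows the neo4j-admin import header convention: node
files carry ``<key>:ID``, typed property columns (``:int``, ``:float``,
``:boolean``, ``:string[]`` with ';'-delimited arrays) and a ``:LABEL``
column; relationship files carry ``:START_ID``, ``:END_ID``, ``:TYPE`` and
property columns.  Output is UTF-8 with LF line endings, RFC-4180 quoting,
and byte-stable for a given graph (rows sorted by key).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import ExportError
from .model import (
    CHEMICAL,
    ENZYME,
    LABELS,
    ORGANISM,
    REACTION,
    ChemicalEntity,
    EnzymeEntity,
    KnowledgeGraph,
    OrganismEntity,
    Participant,
    ReactionEntity,
    Relationship,
)

logger = logging.getLogger(__name__)

MANIFEST = "manifest.json"
ARRAY_SEP = ";"

# per-label scalar columns: (column header, attribute)
_NODE_COLUMNS = {
    ORGANISM: [
        ("taxonomy:ID", "taxonomy"),
        ("name", "name"),
        ("names:string[]", "names"),
        ("parent_taxonomy", "parent_taxonomy"),
    ],
    ENZYME: [
        ("uniprot:ID", "uniprot"),
        ("entry", "entry"),
        ("name", "name"),
        ("names:string[]", "names"),
        ("ec_code:string[]", "ec_code"),
    ],
    REACTION: [
        ("id:ID", "id"),
        ("name", "name"),
        ("ec:string[]", "ec"),
        ("balance:boolean", "balance"),
        ("source", "source"),
    ],
    CHEMICAL: [
        ("id:ID", "id"),
        ("name", "name"),
        ("names:string[]", "names"),
        ("formula", "formula"),
        ("charge:int", "charge"),
        ("monoisotopic_mass:float", "monoisotopic_mass"),
        ("inchi", "inchi"),
        ("smiles", "smiles"),
        ("source", "source"),
    ],
}

_NODE_FILES = {
    ORGANISM: "nodes_organism.csv",
    ENZYME: "nodes_enzyme.csv",
    REACTION: "nodes_reaction.csv",
    CHEMICAL: "nodes_chemical.csv",
}


def _cell(value, header: str) -> str:
    if value is None or value == "":
        return ""
    if header.endswith(":string[]"):
        return ARRAY_SEP.join(value)
    if header.endswith(":boolean"):
        return "true" if value else "false"
    if header.endswith(":float"):
        return repr(float(value))
    return str(value)


def _parse_cell(text: str, header: str):
    if text == "":
        return [] if header.endswith(":string[]") else None
    if header.endswith(":string[]"):
        return text.split(ARRAY_SEP)
    if header.endswith(":int"):
        return int(text)
    if header.endswith(":float"):
        return float(text)
    if header.endswith(":boolean"):
        return text == "true"
    return text


def write_bulk_csv(graph: KnowledgeGraph, out_dir: Path) -> dict:
    """Write one nodes file per label and one relationships file per edge
    type; returns (and writes) a manifest of files with row counts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": []}

    for label in LABELS:
        columns = list(_NODE_COLUMNS[label])
        if label in (CHEMICAL, REACTION):
            namespaces = sorted(
                {ns for ent in graph.nodes[label].values()
                 for ns in ent.xrefs}
            )
            columns += [(ns, ("xrefs", ns)) for ns in namespaces]
        headers = [h for h, _ in columns] + [":LABEL"]
        path = out_dir / _NODE_FILES[label]
        n = 0
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(headers)
            for key in sorted(graph.nodes[label]):
                ent = graph.nodes[label][key]
                row = []
                for header, attr in columns:
                    if isinstance(attr, tuple):
                        value = ent.xrefs.get(attr[1])
                    else:
                        value = getattr(ent, attr)
                    row.append(_cell(value, header))
                writer.writerow(row + [label])
                n += 1
        manifest["files"].append(
            {"path": path.name, "kind": "nodes", "label": label, "rows": n}
        )

    by_type: dict[str, list[Relationship]] = {}
    for rel in graph.relationships:
        by_type.setdefault(rel.type, []).append(rel)
    for rtype in sorted(by_type):
        rels = by_type[rtype]
        prop_keys = sorted({k for rel in rels for k in rel.props})
        headers = [":START_ID", ":END_ID", ":TYPE"] + [
            f"{k}:int" if k == "stoichiometry" else k for k in prop_keys
        ]
        path = out_dir / f"rel_{rtype}.csv"
        rows = sorted(
            (
                [rel.from_id, rel.to_id, rtype]
                + [_cell(rel.props.get(k),
                         "stoichiometry:int" if k == "stoichiometry" else k)
                   for k in prop_keys]
            )
            for rel in rels
        )
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(headers)
            writer.writerows(rows)
        manifest["files"].append(
            {"path": path.name, "kind": "relationships", "type": rtype,
             "rows": len(rows)}
        )

    (out_dir / MANIFEST).write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return manifest


_ENTITY_BUILDERS = {
    ORGANISM: OrganismEntity,
    ENZYME: EnzymeEntity,
    REACTION: ReactionEntity,
    CHEMICAL: ChemicalEntity,
}


def read_bulk_csv(dir: Path) -> KnowledgeGraph:
    """Rebuild a graph from a bulk-CSV directory written by
    :func:`write_bulk_csv`; inverse up to canonical ordering."""
    dir = Path(dir)
    manifest_path = dir / MANIFEST
    if not manifest_path.exists():
        raise ExportError(f"no {MANIFEST} in {dir}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    graph = KnowledgeGraph()
    rel_entries = []
    for entry in manifest["files"]:
        path = dir / entry["path"]
        if not path.exists():
            raise ExportError(f"manifest file {entry['path']} missing")
        if entry["kind"] == "relationships":
            rel_entries.append((entry, path))
            continue
        label = entry["label"]
        known = {h: attr for h, attr in _NODE_COLUMNS[label]}
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            headers = next(reader)
            for row in reader:
                kwargs = {}
                xrefs: dict[str, str] = {}
                extra: dict[str, str] = {}
                for header, text in zip(headers, row):
                    if header == ":LABEL":
                        continue
                    value = _parse_cell(text, header)
                    if header in known:
                        if value is None and header.endswith(":string[]"):
                            value = []
                        field = known[header]
                        if value is not None:
                            kwargs[field] = value
                    elif value is not None:
                        from .model import (
                            CHEMICAL_XREF_NAMESPACES,
                            REACTION_XREF_NAMESPACES,
                        )
                        if header in (CHEMICAL_XREF_NAMESPACES
                                      | REACTION_XREF_NAMESPACES):
                            xrefs[header] = value
                        else:
                            logger.warning(
                                "unknown column %r kept as string property",
                                header,
                            )
                            extra[header] = value
                ent = _ENTITY_BUILDERS[label](**kwargs)
                if xrefs:
                    ent.xrefs = xrefs
                if extra:
                    ent.extra = extra  # loose attribute: forward compat
                graph.upsert_node(label, ent)
    for entry, path in rel_entries:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            headers = next(reader)
            for row in reader:
                record = dict(zip(headers, row))
                props = {}
                for header, text in record.items():
                    if header.startswith(":") or text == "":
                        continue
                    key = header.split(":", 1)[0]
                    props[key] = _parse_cell(
                        text, header if ":" in header else key
                    )
                graph.add_relationship(
                    Relationship.make(
                        record[":START_ID"], record[":END_ID"],
                        record[":TYPE"], **props,
                    )
                )
    # participants live on reaction entities as well as edges
    for rxn in graph.nodes[REACTION].values():
        participants = []
        for role, etype in (("reactant", "has_reactant"),
                            ("cofactor", "has_cofactor")):
            for rel in graph.out_edges(rxn.id, etype):
                s = rel.props.get("stoichiometry")
                if s is not None:
                    participants.append(Participant(rel.to_id, s, role))
        rxn.participants = sorted(
            participants, key=lambda p: (p.chemical_id, p.stoichiometry)
        )
    graph.check_integrity()
    return graph


# ---------------------------------------------------------------------------
# query-result writers
# ---------------------------------------------------------------------------

Rows = Union[pd.DataFrame, Iterable[dict]]


def _as_frame(rows: Rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(list(rows))


def write_results(rows: Rows, format: str, path: Path) -> None:
    """Write homogeneous result rows as RFC-4180 CSV (with header) or as a
    JSON array of objects."""
    frame = _as_frame(rows)
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(frame.columns)
            for row in frame.itertuples(index=False):
                writer.writerow(
                    ["" if pd.isna(v) else v for v in row]
                )
    elif format == "json":
        records = json.loads(frame.to_json(orient="records"))
        path.write_text(
            json.dumps(records, indent=1) + "\n", encoding="utf-8"
        )
    else:
        raise ExportError(f"unknown result format {format!r}")


def read_results(path: Path, format: str) -> pd.DataFrame:
    """Inverse of :func:`write_results` (all-string cells for CSV)."""
    path = Path(path)
    if format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            headers = next(reader)
            return pd.DataFrame(list(reader), columns=headers)
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    raise ExportError(f"unknown result format {format!r}")
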