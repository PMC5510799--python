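"""Cross-reference namespace normalisation and entity merging.

Different source databases name the same external resource differently —
a ChEBI dump says "KEGG COMPOUND accession" where an MNXref dump says
"kegg" — so every cross-reference namespace token is first mapped onto a
canonical identifiers.org key (``kegg.compound``, ``chebi``, ``mnx``, ...).
Entities from different sources that then share any (namespace, accession)
pair are merged transitively, so each real-world entity appears exactly
once in the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import UnmappedNamespaceError
from .model import (
    CHEMICAL,
    CHEMICAL_XREF_NAMESPACES,
    REACTION,
    REACTION_XREF_NAMESPACES,
)

logger = logging.getLogger(__name__)

# context-free identity tokens: every canonical identifiers.org key maps to
# itself regardless of node label
_IDENTITY = {ns: ns for ns in CHEMICAL_XREF_NAMESPACES
             | REACTION_XREF_NAMESPACES}

#: token (lower-case) -> key, or -> {context -> key} when ambiguous
DEFAULT_NAMESPACE_MAP: dict[str, object] = {
    **_IDENTITY,
    "kegg compound accession": "kegg.compound",
    "kegg reaction accession": "kegg.reaction",
    "kegg drug accession": "kegg.drug",
    "kegg glycan accession": "kegg.glycan",
    "kegg": {CHEMICAL: "kegg.compound", REACTION: "kegg.reaction"},
    "keggc": "kegg.compound",
    "keggr": "kegg.reaction",
    "mnxref": "mnx",
    "metanetx.chemical": "mnx",
    "metanetx.reaction": "mnx",
    "bigg": {CHEMICAL: "bigg.metabolite", REACTION: "bigg.reaction"},
    "seed": {CHEMICAL: "seed.compound", REACTION: "seed"},
    "cas registry number": "cas",
    "chebi accession": "chebi",
    "hmdb accession": "hmdb",
    "lipid maps instance accession": "lipidmaps",
}


class NamespaceMap:
    """Maps source-local namespace tokens to identifiers.org keys.

    Lookup is case-insensitive; a node-label context disambiguates tokens
    like ``kegg`` that resolve differently for chemicals and reactions.
    Unknown tokens raise :class:`UnmappedNamespaceError` — never silent
    pass-through.
    """

    def __init__(self, extensions: Optional[dict[str, object]] = None):
        self._table = dict(DEFAULT_NAMESPACE_MAP)
        if extensions:
            self._table.update(
                {k.lower(): v for k, v in extensions.items()}
            )

    def normalize(self, token: str, context: str = CHEMICAL) -> str:
        if not token:
            raise UnmappedNamespaceError(token, context)
        entry = self._table.get(token.strip().lower())
        if isinstance(entry, dict):
            entry = entry.get(context)
        if entry is None:
            raise UnmappedNamespaceError(token, context)
        return entry


_DEFAULT_MAP = NamespaceMap()


def normalize_namespace_key(token: str, context: str = CHEMICAL) -> str:
    """Resolve a namespace token against the default map."""
    return _DEFAULT_MAP.normalize(token, context)


def normalize_xref(
    raw_namespace: str, raw_accession: str, context: str = CHEMICAL,
    namespace_map: Optional[NamespaceMap] = None,
) -> tuple[str, str]:
    """Normalise a (namespace token, accession) pair.

    ChEBI accessions are canonicalised to the ``CHEBI:<n>`` form so the
    bare-number spelling used by some sources matches the prefixed one.
    """
    nsmap = namespace_map or _DEFAULT_MAP
    ns = nsmap.normalize(raw_namespace, context)
    acc = raw_accession.strip()
    if ns == "chebi" and not acc.upper().startswith("CHEBI:"):
        acc = f"CHEBI:{acc}"
    elif ns == "chebi":
        acc = "CHEBI:" + acc.split(":", 1)[1]
    return ns, acc


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

#: source precedence per label: earlier wins property conflicts and supplies
#: the canonical node key
DEFAULT_PRECEDENCE: dict[str, tuple[str, ...]] = {
    CHEMICAL: ("chebi", "mnxref"),
    REACTION: ("mnxref", "kegg"),
}


@dataclass
class MergeReport:
    """Record of what merging did: key remapping plus property conflicts."""

    merge_map: dict[str, str] = field(default_factory=dict)
    #: (canonical key, property, kept value, dropped value, winning source)
    conflicts: list[tuple[str, str, object, object, str]] = field(
        default_factory=list
    )

    def to_csv(self, path: Path) -> None:
        frame = pd.DataFrame(
            self.conflicts,
            columns=["key", "property", "kept", "dropped", "winning_source"],
        )
        frame.to_csv(path, index=False)

    def merge_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.merge_map.items()),
            columns=["original_key", "canonical_key"],
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


_SCALAR_FIELDS = ("name", "formula", "charge", "monoisotopic_mass", "inchi",
                  "smiles", "balance", "entry")


def merge_entities(
    entities: Sequence, precedence: Optional[Sequence[str]] = None
) -> tuple[list, MergeReport]:
    """Merge same-label entities that share any (namespace, accession) pair.

    Merging is transitive (connected components over shared xrefs via
    union-find).  Within a component the highest-precedence source supplies
    the canonical key and wins scalar property conflicts; losing values are
    logged.  Cross-reference maps are unioned; a namespace carried with two
    different accessions is kept from the winner and logged as a conflict.
    Idempotent: no two output entities share an xref pair.
    """
    entities = list(entities)
    if not entities:
        return [], MergeReport()
    label = entities[0].label
    if precedence is None:
        precedence = DEFAULT_PRECEDENCE.get(label, ())
    rank = {src: i for i, src in enumerate(precedence)}

    uf = _UnionFind(len(entities))
    first_seen: dict[tuple[str, str], int] = {}
    for i, ent in enumerate(entities):
        for pair in ent.xrefs.items():
            j = first_seen.setdefault(pair, i)
            if j != i:
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(entities)):
        components.setdefault(uf.find(i), []).append(i)

    merged: list = []
    report = MergeReport()
    for root in sorted(components):
        members = sorted(
            components[root],
            key=lambda i: (rank.get(entities[i].source, len(rank)), i),
        )
        winner = entities[members[0]]
        if len(members) == 1:
            merged.append(winner)
            continue
        out = replace(winner)
        out.xrefs = dict(winner.xrefs)
        if hasattr(out, "names"):
            out.names = list(winner.names)
        for i in members[1:]:
            other = entities[i]
            report.merge_map[other.key] = winner.key
            for f in _SCALAR_FIELDS:
                if not hasattr(out, f):
                    continue
                kept, new = getattr(out, f), getattr(other, f)
                if kept in (None, "") and new not in (None, ""):
                    setattr(out, f, new)
                elif (new not in (None, "") and new != kept):
                    report.conflicts.append(
                        (winner.key, f, kept, new, winner.source)
                    )
                    if f == "name" and hasattr(out, "names") \
                            and new not in out.names:
                        out.names.append(new)
            for syn in getattr(other, "names", []):
                if syn not in out.names:
                    out.names.append(syn)
            for ns, acc in other.xrefs.items():
                if ns in out.xrefs and out.xrefs[ns] != acc:
                    report.conflicts.append(
                        (winner.key, f"xref:{ns}", out.xrefs[ns], acc,
                         winner.source)
                    )
                else:
                    out.xrefs.setdefault(ns, acc)
        merged.append(out)
    return merged, report


# ---------------------------------------------------------------------------
# build orchestration
# ---------------------------------------------------------------------------

@dataclass
class BuildConfig:
    """Build-time settings, loadable from a YAML key-value file.

    ``balance_addable_species`` lists (formula, charge) pairs the balancer
    may introduce; the matching chemical nodes are located in the graph by
    formula and charge at build time.
    """

    namespace_map: dict[str, object] = field(default_factory=dict)
    source_precedence: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PRECEDENCE)
    )
    cofactor_min_pair_count: Optional[int] = None
    balance_addable_species: tuple[tuple[str, int], ...] = (
        ("H", 1), ("H2O", 0),
    )
    balance_max_coefficient: int = 20
    pathway_max_len: int = 8

    @classmethod
    def from_yaml(cls, path: Path) -> "BuildConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        if "namespace_map" in raw:
            cfg.namespace_map = dict(raw["namespace_map"])
        if "source_precedence" in raw:
            cfg.source_precedence = {
                k: tuple(v) for k, v in raw["source_precedence"].items()
            }
        if "cofactor" in raw and "min_pair_count" in raw["cofactor"]:
            cfg.cofactor_min_pair_count = int(raw["cofactor"]["min_pair_count"])
        bal = raw.get("balance", {})
        if "addable_species" in bal:
            cfg.balance_addable_species = tuple(
                (str(f), int(c)) for f, c in bal["addable_species"]
            )
        if "max_coefficient" in bal:
            cfg.balance_max_coefficient = int(bal["max_coefficient"])
        if "pathway" in raw and "max_len" in raw["pathway"]:
            cfg.pathway_max_len = int(raw["pathway"]["max_len"])
        return cfg


def build_graph(
    source_dir: Path, config: Optional[BuildConfig] = None
):
    """Parse, normalise, merge, rewire, balance and annotate in one pass.

    Returns ``(KnowledgeGraph, MergeReport, build_log)`` where the build log
    is a list of human-readable notes (missing files, dropped links, balance
    outcomes).  Missing source files yield warnings, not failures; an empty
    directory yields an empty graph.
    """
    from . import balance as balance_mod
    from . import chem as chem_mod
    from . import source_io
    from .model import KnowledgeGraph, Relationship

    config = config or BuildConfig()
    source_dir = Path(source_dir)
    log: list[str] = []
    report = MergeReport()
    graph = KnowledgeGraph()

    def _path(name: str) -> Optional[Path]:
        p = source_dir / name
        if not p.exists():
            log.append(f"warning: missing source file {name}")
            return None
        return p

    # -- parse -------------------------------------------------------------
    organisms: list = []
    is_a_rels: list = []
    nodes_p, names_p = _path(source_io.TAXONOMY_NODES), _path(
        source_io.TAXONOMY_NAMES
    )
    if nodes_p and names_p:
        organisms, is_a_rels = source_io.parse_taxonomy_dump(nodes_p, names_p)

    mnx_chems: list = []
    if (p := _path(source_io.MNX_CHEMICALS)):
        mnx_chems = source_io.parse_mnxref_chemicals(p)

    chebi_chems: list = []
    chem_rels: list = []
    chebi_paths = [_path(n) for n in (
        source_io.CHEBI_COMPOUNDS, source_io.CHEBI_RELATIONS,
        source_io.CHEBI_DATA, source_io.CHEBI_NAMES,
    )]
    if all(chebi_paths):
        chebi_chems, chem_rels = source_io.parse_chebi_ontology(*chebi_paths)

    reactions: list = []
    if (p := _path(source_io.MNX_REACTIONS)):
        reactions = source_io.parse_mnxref_reactions(p)

    # -- merge chemicals (chebi first: it wins precedence by default) ------
    merged_chems, chem_report = merge_entities(
        chebi_chems + mnx_chems,
        config.source_precedence.get(CHEMICAL),
    )
    report.merge_map.update(chem_report.merge_map)
    report.conflicts.extend(chem_report.conflicts)

    merged_rxns, rxn_report = merge_entities(
        reactions, config.source_precedence.get(REACTION)
    )
    report.merge_map.update(rxn_report.merge_map)
    report.conflicts.extend(rxn_report.conflicts)

    def canonical(key: str) -> str:
        return report.merge_map.get(key, key)

    # -- nodes -------------------------------------------------------------
    for org in organisms:
        graph.upsert_node("Organism", org)
    for chem in merged_chems:
        graph.upsert_node(CHEMICAL, chem)
    for rxn in merged_rxns:
        rxn.participants = [
            replace(part, chemical_id=canonical(part.chemical_id))
            for part in rxn.participants
        ]
        graph.upsert_node(REACTION, rxn)

    # -- proteins ----------------------------------------------------------
    reaction_index: dict[tuple[str, str], str] = {}
    for rxn in merged_rxns:
        for ns, acc in rxn.xrefs.items():
            reaction_index.setdefault((ns, acc), rxn.id)
    enzymes: list = []
    expresses: list = []
    catalysed_by: list = []
    deferred: list = []
    if (p := _path(source_io.PROTEINS)):
        enzymes, expresses, catalysed_by, deferred = (
            source_io.parse_protein_table(p, reaction_index)
        )
    for enz in enzymes:
        graph.upsert_node("Enzyme", enz)
    for link in deferred:
        log.append(
            f"warning: unresolved reaction xref {link.namespace}:"
            f"{link.accession} for enzyme {link.uniprot}; edge dropped"
        )

    # -- relationships (rewired to canonical keys) -------------------------
    def _try_add(rel: Relationship, what: str) -> None:
        rel = Relationship(
            canonical(rel.from_id), canonical(rel.to_id), rel.type,
            rel.properties,
        )
        try:
            graph.add_relationship(rel)
        except Exception as exc:  # noqa: BLE001 - logged, build continues
            log.append(f"warning: dropped {what} {rel.from_id}->"
                       f"{rel.to_id}: {exc}")

    for rel in is_a_rels:
        _try_add(rel, "taxonomy edge")
    for rel in chem_rels:
        _try_add(rel, "ontology edge")
    for rel in expresses:
        _try_add(rel, "expresses edge")
    for rel in catalysed_by:
        _try_add(rel, "catalysed_by edge")
    for rxn in merged_rxns:
        for part in rxn.participants:
            _try_add(
                Relationship.make(rxn.id, part.chemical_id, "has_reactant",
                                  stoichiometry=part.stoichiometry),
                "participant edge",
            )

    # -- balancing pass (before cofactor annotation, so that added protons
    #    and water are themselves classified as cofactors) ------------------
    chemicals = graph.nodes[CHEMICAL]
    addable = []
    for formula, charge in config.balance_addable_species:
        target = chem_mod.parse_formula(formula)
        for chem in chemicals.values():
            if chem.charge != charge or not chem.formula:
                continue
            try:
                if chem_mod.parse_formula(chem.formula).counts == target.counts:
                    addable.append((chem.id, formula, charge))
                    break
            except chem_mod.FormulaError:
                continue
    bal_config = balance_mod.BalanceConfig(
        addable_species=tuple(addable),
        max_coefficient=config.balance_max_coefficient,
    )
    n_rebalanced = 0
    for rxn in graph.nodes[REACTION].values():
        result = balance_mod.balance_reaction(rxn, chemicals, bal_config)
        if result.status is balance_mod.BalanceStatus.ALREADY_BALANCED:
            rxn.balance = True
        elif result.status is balance_mod.BalanceStatus.REBALANCED:
            rxn.balance = True
            n_rebalanced += 1
            _apply_balance(graph, rxn, result)
            log.append(
                f"rebalanced {rxn.id}: "
                + ", ".join(f"{c} {o}->{n}" for c, o, n in result.delta)
            )
        elif result.status is balance_mod.BalanceStatus.UNBALANCEABLE:
            rxn.balance = False
            log.append(f"unbalanceable reaction {rxn.id}")
        else:
            rxn.balance = None

    n_cof = chem_mod.annotate_cofactors(graph, config.cofactor_min_pair_count)
    log.append(f"relabelled {n_cof} cofactor edges; "
               f"rebalanced {n_rebalanced} reactions")

    graph.check_integrity()
    return graph, report, log


def _apply_balance(graph, rxn, result) -> None:
    """Replace a reaction's participants and participant edges with the
    balancer's corrected stoichiometries."""
    from .model import Relationship

    for edge in list(graph.out_edges(rxn.id, "has_reactant")):
        graph.remove_relationship(edge)
    rxn.participants = result.participants
    for part in rxn.participants:
        graph.add_relationship(
            Relationship.make(rxn.id, part.chemical_id, "has_reactant",
                              stoichiometry=part.stoichiometry)
        )
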