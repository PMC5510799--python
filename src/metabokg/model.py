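"""Domain types and the embedded labelled-property-graph store.

The graph holds four node labels — ``Organism``, ``Enzyme``, ``Reaction`` and
``Chemical`` — connected by a fixed set of directed, typed relationships
(taxonomic ``is_a``, ``expresses``, ``catalysed_by``, ``has_reactant`` /
``has_cofactor`` carrying signed stoichiometries, and the nine
chemical-ontology relation types).  The store is in-memory, insertion-ordered
and deterministic, so exports of the same graph are byte-identical.

Stoichiometry sign convention: negative = consumed (reactant side),
positive = produced (product side), as in constraint-based modelling.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import pandas as pd

from .errors import DanglingEndpointError, SchemaError, ValidationError

# The four node labels.
ORGANISM = "Organism"
ENZYME = "Enzyme"
REACTION = "Reaction"
CHEMICAL = "Chemical"
LABELS = (ORGANISM, ENZYME, REACTION, CHEMICAL)

#: Chemical-to-chemical ontology relation types (ChEBI vocabulary).
CHEMICAL_RELATION_TYPES = (
    "has_functional_parent",
    "has_parent_hydride",
    "has_part",
    "is_a",
    "is_conjugate_acid_of",
    "is_conjugate_base_of",
    "is_enantiomer_of",
    "is_substituent_group_from",
    "is_tautomer_of",
)

#: Allowed (from-label, type, to-label) signatures.
SIGNATURES = frozenset(
    [
        (ORGANISM, "is_a", ORGANISM),
        (ORGANISM, "expresses", ENZYME),
        (REACTION, "catalysed_by", ENZYME),
        (REACTION, "has_reactant", CHEMICAL),
        (REACTION, "has_cofactor", CHEMICAL),
    ]
    + [(CHEMICAL, t, CHEMICAL) for t in CHEMICAL_RELATION_TYPES]
)

#: Cross-reference namespaces accepted on Chemical nodes (identifiers.org keys).
CHEMICAL_XREF_NAMESPACES = frozenset(
    {
        "bigg.metabolite", "cas", "chebi", "chemidplus", "chemspider",
        "drugbank", "hmdb", "kegg.compound", "kegg.drug", "kegg.glycan",
        "knapsack", "lipidmaps", "metacyc", "mnx", "molbase", "pdb",
        "pubmed", "reactome", "resid", "seed.compound", "unipathway",
        "wikipedia.en",
    }
)

#: Cross-reference namespaces accepted on Reaction nodes.
REACTION_XREF_NAMESPACES = frozenset(
    {"bigg.reaction", "kegg.reaction", "metacyc", "mnx", "reactome", "rhea",
     "seed"}
)


@dataclass
class Participant:
    """A chemical taking part in a reaction.

    ``stoichiometry`` is a non-zero signed integer: < 0 consumed, > 0 produced.
    ``role`` is ``"reactant"`` until cofactor annotation relabels it.
    """

    chemical_id: str
    stoichiometry: int
    role: str = "reactant"

    def __post_init__(self):
        if not isinstance(self.stoichiometry, int) or self.stoichiometry == 0:
            raise ValidationError(
                f"participant {self.chemical_id!r}: stoichiometry must be a "
                f"non-zero integer, got {self.stoichiometry!r}"
            )
        if self.role not in ("reactant", "cofactor"):
            raise ValidationError(f"unknown participant role {self.role!r}")


@dataclass
class ChemicalEntity:
    """A chemical species or class (generic classes lack formula/mass)."""

    id: str
    name: str = ""
    names: list[str] = field(default_factory=list)
    formula: Optional[str] = None
    charge: Optional[int] = None
    monoisotopic_mass: Optional[float] = None
    inchi: Optional[str] = None
    smiles: Optional[str] = None
    xrefs: dict[str, str] = field(default_factory=dict)
    source: str = ""

    label = CHEMICAL

    @property
    def key(self) -> str:
        return self.id

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("Chemical requires a non-empty id")
        if self.charge is not None and not isinstance(self.charge, int):
            raise ValidationError(
                f"Chemical {self.id}: charge must be an integer"
            )
        if self.formula is not None:
            # deferred import: avoids a model <-> chem cycle
            from .chem import parse_formula
            from .errors import FormulaError, GenericFormulaError

            try:
                parse_formula(self.formula)
            except GenericFormulaError:
                pass  # polymer/class formulas are legal, just massless
            except FormulaError as exc:
                raise ValidationError(
                    f"Chemical {self.id}: {exc}"
                ) from exc
        unknown = set(self.xrefs) - CHEMICAL_XREF_NAMESPACES
        if unknown:
            raise ValidationError(
                f"Chemical {self.id}: unknown xref namespaces {sorted(unknown)}"
            )


@dataclass
class ReactionEntity:
    """A reaction over signed-integer participants with a balance flag.

    ``balance`` is tri-state: True, False or None (unknown — e.g. a
    participant lacks formula or charge).
    """

    id: str
    name: str = ""
    ec: list[str] = field(default_factory=list)
    balance: Optional[bool] = None
    xrefs: dict[str, str] = field(default_factory=dict)
    source: str = ""
    participants: list[Participant] = field(default_factory=list)

    label = REACTION

    @property
    def key(self) -> str:
        return self.id

    def validate(self) -> None:
        if not self.id:
            raise ValidationError("Reaction requires a non-empty id")
        for p in self.participants:
            if not isinstance(p.stoichiometry, int) or p.stoichiometry == 0:
                raise ValidationError(
                    f"Reaction {self.id}: participant {p.chemical_id} has "
                    f"invalid stoichiometry {p.stoichiometry!r}"
                )
        unknown = set(self.xrefs) - REACTION_XREF_NAMESPACES
        if unknown:
            raise ValidationError(
                f"Reaction {self.id}: unknown xref namespaces {sorted(unknown)}"
            )

    def is_well_formed(self) -> bool:
        """True iff at least one consumed and one produced participant."""
        return any(p.stoichiometry < 0 for p in self.participants) and any(
            p.stoichiometry > 0 for p in self.participants
        )


@dataclass
class EnzymeEntity:
    """A protein catalyst, keyed by UniProt accession."""

    uniprot: str
    entry: str = ""
    ec_code: list[str] = field(default_factory=list)
    name: str = ""
    names: list[str] = field(default_factory=list)

    label = ENZYME

    @property
    def key(self) -> str:
        return self.uniprot

    def validate(self) -> None:
        if not self.uniprot:
            raise ValidationError("Enzyme requires a non-empty uniprot id")


@dataclass
class OrganismEntity:
    """A taxon, keyed by NCBI Taxonomy id; parent pointers form a tree."""

    taxonomy: str
    name: str = ""
    names: list[str] = field(default_factory=list)
    parent_taxonomy: Optional[str] = None

    label = ORGANISM

    @property
    def key(self) -> str:
        return self.taxonomy

    def validate(self) -> None:
        if not self.taxonomy:
            raise ValidationError("Organism requires a non-empty taxonomy id")


ENTITY_TYPES = {
    ORGANISM: OrganismEntity,
    ENZYME: EnzymeEntity,
    REACTION: ReactionEntity,
    CHEMICAL: ChemicalEntity,
}


@dataclass(frozen=True)
class Relationship:
    """A directed, typed edge with a (hashable) property map.

    Identical (from, to, type, properties) edges dedupe; edges differing in
    any property — e.g. provenance ``source`` — are kept distinct.
    """

    from_id: str
    to_id: str
    type: str
    properties: tuple[tuple[str, object], ...] = ()

    @staticmethod
    def make(from_id: str, to_id: str, type: str, **props) -> "Relationship":
        return Relationship(
            from_id, to_id, type, tuple(sorted(props.items()))
        )

    @property
    def props(self) -> dict:
        return dict(self.properties)


class KnowledgeGraph:
    """Insertion-ordered labelled property graph over the four node labels."""

    def __init__(self) -> None:
        self.nodes: dict[str, dict[str, object]] = {lb: {} for lb in LABELS}
        self._relationships: dict[Relationship, None] = {}  # ordered set
        # adjacency: (node_key -> list of relationships), refreshed lazily
        self._out: dict[str, list[Relationship]] = defaultdict(list)
        self._in: dict[str, list[Relationship]] = defaultdict(list)
        self._label_of: dict[str, str] = {}

    # -- nodes ------------------------------------------------------------

    def upsert_node(self, label: str, entity) -> str:
        """Insert or update a node; re-upserting the same key merges fields.

        Scalar fields already set on the stored entity win; missing scalars
        are filled in, list fields are unioned (order-preserving) and xref
        maps merged.  Returns the node key.
        """
        if label not in LABELS:
            raise SchemaError(f"unknown node label {label!r}")
        if not isinstance(entity, ENTITY_TYPES[label]):
            raise ValidationError(
                f"label {label} requires {ENTITY_TYPES[label].__name__}, "
                f"got {type(entity).__name__}"
            )
        entity.validate()
        key = entity.key
        store = self.nodes[label]
        if key in store:
            store[key] = _merge_entity(store[key], entity)
        else:
            if key in self._label_of and self._label_of[key] != label:
                raise SchemaError(
                    f"key {key!r} already used by label {self._label_of[key]}"
                )
            store[key] = entity
            self._label_of[key] = label
        return key

    def get(self, label: str, key: str):
        return self.nodes[label].get(key)

    def label_of(self, key: str) -> Optional[str]:
        return self._label_of.get(key)

    def n_nodes(self, label: Optional[str] = None) -> int:
        if label is not None:
            return len(self.nodes[label])
        return sum(len(d) for d in self.nodes.values())

    # -- relationships ----------------------------------------------------

    def add_relationship(self, rel: Relationship) -> None:
        from_label = self._label_of.get(rel.from_id)
        to_label = self._label_of.get(rel.to_id)
        if from_label is None:
            raise DanglingEndpointError(f"unknown node {rel.from_id!r}")
        if to_label is None:
            raise DanglingEndpointError(f"unknown node {rel.to_id!r}")
        if (from_label, rel.type, to_label) not in SIGNATURES:
            raise SchemaError(
                f"illegal relationship {from_label}-[{rel.type}]->{to_label}"
            )
        if rel in self._relationships:
            return
        self._relationships[rel] = None
        self._out[rel.from_id].append(rel)
        self._in[rel.to_id].append(rel)

    def remove_relationship(self, rel: Relationship) -> None:
        if rel in self._relationships:
            del self._relationships[rel]
            self._out[rel.from_id].remove(rel)
            self._in[rel.to_id].remove(rel)

    @property
    def relationships(self) -> list[Relationship]:
        return list(self._relationships)

    def n_relationships(self, type: Optional[str] = None) -> int:
        if type is None:
            return len(self._relationships)
        return sum(1 for r in self._relationships if r.type == type)

    def out_edges(self, key: str, type: Optional[str] = None
                  ) -> list[Relationship]:
        rels = self._out.get(key, [])
        return [r for r in rels if type is None or r.type == type]

    def in_edges(self, key: str, type: Optional[str] = None
                 ) -> list[Relationship]:
        rels = self._in.get(key, [])
        return [r for r in rels if type is None or r.type == type]

    def edges_of_type(self, type: str) -> Iterator[Relationship]:
        return (r for r in self._relationships if r.type == type)

    # -- validation & statistics ------------------------------------------

    def check_integrity(self) -> None:
        """Full-scan referential-integrity and signature check."""
        for rel in self._relationships:
            fl = self._label_of.get(rel.from_id)
            tl = self._label_of.get(rel.to_id)
            if fl is None or tl is None:
                raise DanglingEndpointError(
                    f"dangling endpoint on {rel.from_id}-[{rel.type}]->"
                    f"{rel.to_id}"
                )
            if (fl, rel.type, tl) not in SIGNATURES:
                raise SchemaError(
                    f"illegal signature {fl}-[{rel.type}]->{tl}"
                )

    def summary_stats(self) -> pd.DataFrame:
        """Node counts per label and relationship coverage per label pair.

        For every ordered label pair connected by at least one stored edge
        (reported in both orientations), the row gives the edge count, the
        number of distinct pair-first-label nodes taking part in such an
        edge, and that number as a percentage of all nodes of the label.
        """
        rows = []
        for label in LABELS:
            n = len(self.nodes[label])
            if n:
                rows.append(
                    {"item": label, "count": n, "edges": math.nan,
                     "percentage": math.nan}
                )
        # per ordered pair: edge count + distinct participating first-label
        # nodes (both orientations of each stored edge are reported)
        edges: dict[tuple[str, str], int] = defaultdict(int)
        havers: dict[tuple[str, str], set] = defaultdict(set)
        for rel in self._relationships:
            fl = self._label_of[rel.from_id]
            tl = self._label_of[rel.to_id]
            edges[(fl, tl)] += 1
            havers[(fl, tl)].add(rel.from_id)
            if tl != fl:  # same-label pairs report the From side only
                edges[(tl, fl)] += 0  # ensure reverse orientation row exists
                havers[(tl, fl)].add(rel.to_id)
        order = {lb: i for i, lb in enumerate(LABELS)}
        for (a, b) in sorted(edges, key=lambda p: (order[p[0]], order[p[1]])):
            n_from = len(self.nodes[a])
            n_have = len(havers[(a, b)])
            n_edges = edges[(a, b)] or edges[(b, a)]
            rows.append(
                {
                    "item": f"{a}-{b}",
                    "count": n_have,
                    "edges": n_edges,
                    "percentage": 100.0 * n_have / n_from if n_from else 0.0,
                }
            )
        return pd.DataFrame(rows, columns=["item", "count", "edges",
                                           "percentage"])


def _merge_entity(current, incoming):
    """Merge ``incoming`` into ``current`` (same key): first-loaded scalars
    win, lists union preserving order, xref maps merge."""
    updates = {}
    lost_name = None
    for f in current.__dataclass_fields__:
        cur, new = getattr(current, f), getattr(incoming, f)
        if isinstance(cur, list):
            extra = [v for v in new if v not in cur]
            if extra:
                updates[f] = cur + extra
        elif isinstance(cur, dict):
            merged = dict(cur)
            for k, v in new.items():
                merged.setdefault(k, v)
            if merged != cur:
                updates[f] = merged
        elif cur in (None, "") and new not in (None, ""):
            updates[f] = new
        elif f == "name" and new and new != cur:
            # conflicting names: keep first-loaded, demote other to synonym
            lost_name = new
    if lost_name is not None and hasattr(current, "names"):
        names = updates.get("names", list(getattr(current, "names")))
        if lost_name not in names:
            updates["names"] = list(names) + [lost_name]
    return replace(current, **updates) if updates else current
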