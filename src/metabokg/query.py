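"""Cross-domain graph queries: reaction context, ontology descendants,
taxon metabolomes, stoichiometry-directed pathway search and pathway
enzyme collection.

Pathway search treats the Reaction-Chemical ``has_reactant`` edges as an
undirected bipartite graph; direction is supplied solely by the
sign-alternation rule — consecutive edge stoichiometries along a path must
have opposite signs, so every traversal moves reactant (negative) to
product (positive) through each reaction, and each intermediate chemical is
produced by one reaction and consumed by the next.  ``has_cofactor`` edges
are excluded, closing the short-cut routes through currency metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .chem import chemical_mass
from .errors import ValidationError
from .model import (
    CHEMICAL,
    CHEMICAL_RELATION_TYPES,
    KnowledgeGraph,
    Relationship,
)


@dataclass
class Pathway:
    """Alternating chemical/reaction sequence with per-edge stoichiometries.

    ``nodes`` is ``[chem0, rxn1, chem1, ..., rxnK, chemK]``;
    ``stoichiometries`` holds the 2K signed edge values in path order.
    """

    nodes: list[str]
    stoichiometries: list[int]

    @property
    def length(self) -> int:
        """Number of reactions."""
        return len(self.nodes) // 2

    @property
    def chemicals(self) -> list[str]:
        return self.nodes[0::2]

    @property
    def reactions(self) -> list[str]:
        return self.nodes[1::2]

    def validate(self) -> None:
        if len(self.nodes) % 2 == 0 or not self.nodes:
            raise ValidationError("pathway must alternate chem/rxn/.../chem")
        if len(self.stoichiometries) != len(self.nodes) - 1:
            raise ValidationError("one stoichiometry per pathway edge")
        for a, b in zip(self.stoichiometries, self.stoichiometries[1:]):
            if a * b >= 0:
                raise ValidationError(
                    "consecutive pathway stoichiometries must alternate sign"
                )


@dataclass
class Subgraph:
    """A node-key set plus relationship subset of a parent graph."""

    nodes: set[str] = field(default_factory=set)
    relationships: list[Relationship] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.nodes


# ---------------------------------------------------------------------------


def _find_reaction_by_xref(graph: KnowledgeGraph, namespace: str,
                           accession: str) -> Optional[str]:
    for rxn in graph.nodes["Reaction"].values():
        if rxn.xrefs.get(namespace) == accession:
            return rxn.id
    return None


def reaction_context(
    graph: KnowledgeGraph,
    reaction_xref: tuple[str, str],
    taxon_id: str,
) -> Subgraph:
    """Does this reaction occur in this organism? Non-empty iff yes.

    The returned subgraph holds the reaction, its chemicals (reactants and
    cofactors), the enzymes linking it to the organism, the organism and
    its taxonomic parent, and any ontology edges among the returned
    chemicals.
    """
    sub = Subgraph()
    rxn_id = _find_reaction_by_xref(graph, *reaction_xref)
    if rxn_id is None or graph.get("Organism", taxon_id) is None:
        return sub
    # enzymes catalysing the reaction AND expressed by the taxon
    expressed = {
        rel.to_id for rel in graph.out_edges(taxon_id, "expresses")
    }
    enzyme_edges = [
        rel for rel in graph.out_edges(rxn_id, "catalysed_by")
        if rel.to_id in expressed
    ]
    if not enzyme_edges:
        return sub
    sub.nodes.add(rxn_id)
    for rel in enzyme_edges:
        sub.nodes.add(rel.to_id)
        sub.relationships.append(rel)
        for exp in graph.out_edges(taxon_id, "expresses"):
            if exp.to_id == rel.to_id:
                sub.relationships.append(exp)
    sub.nodes.add(taxon_id)
    for rel in graph.out_edges(taxon_id, "is_a"):
        sub.nodes.add(rel.to_id)
        sub.relationships.append(rel)
    chem_ids = set()
    for etype in ("has_reactant", "has_cofactor"):
        for rel in graph.out_edges(rxn_id, etype):
            chem_ids.add(rel.to_id)
            sub.nodes.add(rel.to_id)
            sub.relationships.append(rel)
    for cid in sorted(chem_ids):
        for rel in graph.out_edges(cid):
            if rel.type in CHEMICAL_RELATION_TYPES and rel.to_id in chem_ids:
                sub.relationships.append(rel)
    return sub


def descendant_chemicals(
    graph: KnowledgeGraph, parent_name: str, require_formula: bool = True
) -> pd.DataFrame:
    """All chemicals below a named class in the ontology.

    Transitive closure over the nine chemical relation types, traversed
    against their stored child->parent direction.  Rows are distinct on
    (name, formula, chebi, inchi) and sorted; ``require_formula`` drops
    class nodes without a specific formula.  When several Chemical nodes
    carry the parent name, all serve as roots (listed in
    ``result.attrs["roots"]``).
    """
    roots = [
        c.id for c in graph.nodes[CHEMICAL].values()
        if c.name == parent_name
    ]
    seen: set[str] = set(roots)
    stack = list(roots)
    descendants: list[str] = []
    while stack:
        node = stack.pop()
        for rel in graph.in_edges(node):
            if rel.type not in CHEMICAL_RELATION_TYPES:
                continue
            child = rel.from_id
            if child not in seen:
                seen.add(child)
                descendants.append(child)
                stack.append(child)
    rows = []
    for cid in descendants:
        chem = graph.get(CHEMICAL, cid)
        if require_formula and not chem.formula:
            continue
        rows.append(
            {
                "name": chem.name,
                "formula": chem.formula,
                "chebi": chem.xrefs.get("chebi"),
                "inchi": chem.inchi,
            }
        )
    frame = pd.DataFrame(rows, columns=["name", "formula", "chebi", "inchi"])
    frame = frame.drop_duplicates().sort_values(
        ["name", "formula", "chebi"], na_position="last"
    ).reset_index(drop=True)
    frame.attrs["roots"] = sorted(roots)
    return frame


def taxon_metabolome(
    graph: KnowledgeGraph,
    taxon_id: str,
    mass_min: float,
    mass_max: float,
    transitive: bool = False,
) -> pd.DataFrame:
    """Metabolites in a mass window reachable from every strain of a taxon.

    Follows Chemical <-has_reactant- Reaction -catalysed_by-> Enzyme
    <-expresses- Organism -is_a-> taxon.  The taxon match is one ``is_a``
    hop by default (``transitive`` widens it to the whole subtree).  Mass
    bounds are strict; cofactor edges are excluded.
    """
    if not mass_min < mass_max:
        raise ValidationError("mass_min must be below mass_max")
    strains = {
        rel.from_id for rel in graph.in_edges(taxon_id, "is_a")
    }
    if transitive:
        frontier = list(strains)
        while frontier:
            node = frontier.pop()
            for rel in graph.in_edges(node, "is_a"):
                if rel.from_id not in strains:
                    strains.add(rel.from_id)
                    frontier.append(rel.from_id)
    rows = []
    seen: set[str] = set()
    for org_id in sorted(strains):
        for exp in graph.out_edges(org_id, "expresses"):
            for cat in graph.in_edges(exp.to_id, "catalysed_by"):
                for part in graph.out_edges(cat.from_id, "has_reactant"):
                    cid = part.to_id
                    if cid in seen:
                        continue
                    seen.add(cid)
                    chem = graph.get(CHEMICAL, cid)
                    mass = chemical_mass(chem)
                    if mass is None or not (mass_min < mass < mass_max):
                        continue
                    rows.append(
                        {
                            "name": chem.name,
                            "monoisotopic_mass": mass,
                            "formula": chem.formula,
                            "charge": chem.charge,
                        }
                    )
    frame = pd.DataFrame(
        rows, columns=["name", "monoisotopic_mass", "formula", "charge"]
    )
    return frame.drop_duplicates().sort_values(
        ["monoisotopic_mass", "name"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pathway search
# ---------------------------------------------------------------------------


def host_source_chemicals(
    graph: KnowledgeGraph, host_taxon_id: str, produced_only: bool = False
) -> set[str]:
    """Chemicals attached by ``has_reactant`` to reactions catalysed by
    enzymes the host expresses (either sign unless ``produced_only``)."""
    sources: set[str] = set()
    for exp in graph.out_edges(host_taxon_id, "expresses"):
        for cat in graph.in_edges(exp.to_id, "catalysed_by"):
            for part in graph.out_edges(cat.from_id, "has_reactant"):
                stoich = part.props.get("stoichiometry", 0)
                if produced_only and stoich <= 0:
                    continue
                sources.add(part.to_id)
    return sources


def _reactant_adjacency(graph: KnowledgeGraph):
    """Undirected bipartite adjacency over has_reactant edges with signed
    stoichiometries."""
    chem_adj: dict[str, list[tuple[str, int]]] = {}
    rxn_adj: dict[str, list[tuple[str, int]]] = {}
    for rel in graph.edges_of_type("has_reactant"):
        s = rel.props.get("stoichiometry")
        if s is None:
            continue
        rxn_adj.setdefault(rel.from_id, []).append((rel.to_id, s))
        chem_adj.setdefault(rel.to_id, []).append((rel.from_id, s))
    for adj in (chem_adj, rxn_adj):
        for lst in adj.values():
            lst.sort()
    return chem_adj, rxn_adj


def find_pathways(
    graph: KnowledgeGraph,
    host_taxon_id: str,
    target_chemical_id: str,
    max_len: int = 8,
    all_shortest: bool = True,
    produced_only: bool = False,
) -> list[Pathway]:
    """Shortest sign-valid pathways from any host-native chemical to the
    target.

    Paths are simple (no repeated node), at most ``max_len`` reactions
    long, traverse only ``has_reactant`` edges, and satisfy the
    sign-alternation rule at every consecutive edge pair.  All minimum-
    length pathways are returned (lexicographic node order) unless
    ``all_shortest`` is False, in which case only the first is.  A target
    that is itself host-native yields one length-0 pathway.
    """
    if graph.get(CHEMICAL, target_chemical_id) is None:
        raise ValidationError(
            f"target chemical {target_chemical_id!r} not in graph"
        )
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    sources = host_source_chemicals(graph, host_taxon_id, produced_only)
    if target_chemical_id in sources:
        return [Pathway([target_chemical_id], [])]
    chem_adj, rxn_adj = _reactant_adjacency(graph)

    results: list[Pathway] = []

    def dfs(chem: str, last_sign: Optional[int], visited: set[str],
            nodes: list[str], stoichs: list[int], remaining: int) -> None:
        if remaining == 0:
            return
        for rxn, s_out in chem_adj.get(chem, ()):
            if rxn in visited:
                continue
            if last_sign is not None and last_sign * s_out >= 0:
                continue
            for nxt, s_in in rxn_adj.get(rxn, ()):
                if nxt in visited or s_out * s_in >= 0:
                    continue
                if nxt == target_chemical_id:
                    results.append(
                        Pathway(nodes + [rxn, nxt],
                                stoichs + [s_out, s_in])
                    )
                    continue
                visited.add(rxn)
                visited.add(nxt)
                dfs(nxt, s_in, visited, nodes + [rxn, nxt],
                    stoichs + [s_out, s_in], remaining - 1)
                visited.discard(rxn)
                visited.discard(nxt)

    for k in range(1, max_len + 1):
        for src in sorted(sources):
            if src == target_chemical_id:
                continue
            dfs(src, None, {src}, [src], [], k)
        if results:
            break

    # keep only the minimum length (a depth-k sweep may emit shorter hits
    # repeatedly, so dedupe) and order deterministically
    unique = {tuple(p.nodes): p for p in results}
    pathways = sorted(unique.values(), key=lambda p: p.nodes)
    min_len = min((p.length for p in pathways), default=0)
    pathways = [p for p in pathways if p.length == min_len]
    for p in pathways:
        p.validate()
    return pathways if all_shortest else pathways[:1]


def pathway_enzymes(
    graph: KnowledgeGraph, pathways: list[Pathway]
) -> pd.DataFrame:
    """Enzymes (and their organisms) catalysing every pathway reaction.

    One row per (reaction, enzyme, organism); reactions with no enzyme and
    enzymes with no expressing organism yield rows with the missing fields
    empty.
    """
    rxn_ids: list[str] = []
    for p in pathways:
        for rid in p.reactions:
            if rid not in rxn_ids:
                rxn_ids.append(rid)
    rows = []
    for rid in rxn_ids:
        cats = graph.out_edges(rid, "catalysed_by")
        if not cats:
            rows.append({"reaction_id": rid, "enzyme_id": "",
                         "organism_taxonomy": ""})
            continue
        for cat in cats:
            exps = graph.in_edges(cat.to_id, "expresses")
            if not exps:
                rows.append({"reaction_id": rid, "enzyme_id": cat.to_id,
                             "organism_taxonomy": ""})
                continue
            for exp in exps:
                rows.append(
                    {"reaction_id": rid, "enzyme_id": cat.to_id,
                     "organism_taxonomy": exp.from_id}
                )
    return pd.DataFrame(
        rows, columns=["reaction_id", "enzyme_id", "organism_taxonomy"]
    ).drop_duplicates().reset_index(drop=True)
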