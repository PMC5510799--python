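"""The five query patterns, cross-checked against brute-force oracles."""

import pytest

from metabokg.errors import ValidationError
from metabokg.model import (
    ChemicalEntity,
    EnzymeEntity,
    KnowledgeGraph,
    OrganismEntity,
    Participant,
    ReactionEntity,
    Relationship,
)
from metabokg.query import (
    Pathway,
    descendant_chemicals,
    find_pathways,
    pathway_enzymes,
    reaction_context,
    taxon_metabolome,
)
from metabokg.synthetic import (
    random_reaction_network,
    strain_metabolome,
)
from oracles import brute_force_pathways, closure_descendants


class TestReactionContext:
    def test_glucokinase_in_k12(self, glucokinase_graph):
        sub = reaction_context(
            glucokinase_graph, ("kegg.reaction", "R00299"), "83333")
        assert not sub.is_empty()
        types = [r.type for r in sub.relationships]
        assert types.count("has_reactant") == 2
        assert types.count("has_cofactor") == 2
        assert "P0A6V8" in sub.nodes          # Glucokinase links them
        assert {"83333", "562"} <= sub.nodes  # organism and its parent
        assert "has_functional_parent" in types  # edge among the chemicals

    def test_taxon_without_linking_enzyme_gives_empty(self, glucokinase_graph):
        assert reaction_context(
            glucokinase_graph, ("kegg.reaction", "R00299"), "562").is_empty()

    def test_unknown_reaction_xref_gives_empty(self, glucokinase_graph):
        assert reaction_context(
            glucokinase_graph, ("kegg.reaction", "R99999"), "83333").is_empty()


def _toy_ontology():
    g = KnowledgeGraph()
    g.upsert_node("Chemical", ChemicalEntity("F", "flavonoid"))
    g.upsert_node("Chemical", ChemicalEntity("FV", "flavone"))
    g.upsert_node("Chemical", ChemicalEntity(
        "AP", "apigenin", formula="C15H10O5"))
    g.add_relationship(Relationship.make("FV", "F", "is_a"))
    g.add_relationship(Relationship.make("AP", "FV", "is_a"))
    return g


class TestDescendantChemicals:
    def test_formula_filter_on_three_level_chain(self):
        g = _toy_ontology()
        rows = descendant_chemicals(g, "flavonoid", require_formula=True)
        assert rows["name"].tolist() == ["apigenin"]
        rows_all = descendant_chemicals(g, "flavonoid", require_formula=False)
        assert sorted(rows_all["name"]) == ["apigenin", "flavone"]

    def test_cycles_terminate_with_each_node_once(self):
        g = _toy_ontology()
        g.add_relationship(Relationship.make("F", "AP", "has_part"))  # cycle
        rows = descendant_chemicals(g, "flavonoid", require_formula=False)
        assert len(rows) == 2

    def test_multiple_roots_all_used_and_reported(self):
        g = _toy_ontology()
        g.upsert_node("Chemical", ChemicalEntity("F2", "flavonoid"))
        g.upsert_node("Chemical", ChemicalEntity(
            "X", "extra", formula="C2H6"))
        g.add_relationship(Relationship.make("X", "F2", "is_a"))
        rows = descendant_chemicals(g, "flavonoid", require_formula=True)
        assert sorted(rows["name"]) == ["apigenin", "extra"]
        assert rows.attrs["roots"] == ["F", "F2"]

    def test_matches_matrix_power_closure(self, built):
        graph = built[0]
        roots = [c.id for c in graph.nodes["Chemical"].values()
                 if c.name == "water"]
        expected = closure_descendants(graph, roots)
        rows = descendant_chemicals(graph, "water", require_formula=False)
        names = {graph.get("Chemical", cid).name for cid in expected}
        assert set(rows["name"]) == names


class TestTaxonMetabolome:
    def test_strain_pattern_and_strict_bounds(self):
        g = strain_metabolome(n_in_window=11, n_decoys=8)
        rows = taxon_metabolome(g, "562", 400.0, 500.0)
        assert len(rows) == 11
        # decoys sit exactly on the bounds or outside; strict comparison
        assert ((rows["monoisotopic_mass"] > 400)
                & (rows["monoisotopic_mass"] < 500)).all()

    def test_narrow_window_excludes_all(self):
        g = strain_metabolome(n_in_window=11, n_decoys=8)
        assert taxon_metabolome(g, "562", 400.0, 400.1).empty

    def test_widening_the_window_never_shrinks_the_result(self):
        g = strain_metabolome(n_in_window=11, n_decoys=8)
        narrow = taxon_metabolome(g, "562", 420.0, 460.0)
        wide = taxon_metabolome(g, "562", 400.0, 500.0)
        assert set(narrow["name"]) <= set(wide["name"])

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            taxon_metabolome(KnowledgeGraph(), "562", 500.0, 400.0)


def _chain_graph(signs=((-1, 1), (-1, 1))):
    """host -> E1 -> r1; chain S -r1- M -r2- T with configurable signs."""
    g = KnowledgeGraph()
    g.upsert_node("Organism", OrganismEntity("9"))
    g.upsert_node("Enzyme", EnzymeEntity("E1"))
    for cid in ("S", "M", "T"):
        g.upsert_node("Chemical", ChemicalEntity(cid))
    (s1, p1), (s2, p2) = signs
    r1 = ReactionEntity("r1", participants=[
        Participant("S", s1), Participant("M", p1)])
    r2 = ReactionEntity("r2", participants=[
        Participant("M", s2), Participant("T", p2)])
    for rxn in (r1, r2):
        g.upsert_node("Reaction", rxn)
        for p in rxn.participants:
            g.add_relationship(Relationship.make(
                rxn.id, p.chemical_id, "has_reactant",
                stoichiometry=p.stoichiometry))
    g.add_relationship(Relationship.make("r1", "E1", "catalysed_by",
                                         source="x"))
    g.add_relationship(Relationship.make("9", "E1", "expresses", source="x"))
    return g


class TestFindPathways:
    def test_two_step_chain_found(self):
        g = _chain_graph()
        # S and M are host-native (attached to r1); M -r2- T is one step
        (p,) = find_pathways(g, "9", "T")
        assert p.nodes == ["M", "r2", "T"]
        assert p.length == 1

    def test_sign_violation_rejected(self):
        # r2 produces both M and T: entering M (+) then leaving M (+) fails
        g = _chain_graph(signs=((-1, 1), (2, 1)))
        assert find_pathways(g, "9", "T") == []

    def test_target_in_source_set_gives_length_zero(self):
        g = _chain_graph()
        (p,) = find_pathways(g, "9", "M")
        assert p.nodes == ["M"] and p.length == 0

    def test_absent_target_is_an_error(self):
        with pytest.raises(ValidationError, match="NOPE"):
            find_pathways(_chain_graph(), "9", "NOPE")

    def test_pathway_invariants_validated(self):
        with pytest.raises(ValidationError):
            Pathway(["a", "r", "b"], [1, 1]).validate()
        Pathway(["a", "r", "b"], [-1, 1]).validate()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        g = random_reaction_network(n_chemicals=18, n_reactions=18,
                                    seed=seed)
        targets = sorted(g.nodes["Chemical"])[::6]
        for target in targets:
            expected = brute_force_pathways(g, "9000", target, max_len=6)
            got = find_pathways(g, "9000", target, max_len=6)
            assert sorted(p.nodes for p in got) == expected


class TestPathwayEnzymes:
    def test_rows_for_each_catalysing_pair(self, glucokinase_graph):
        pathways = [Pathway(
            ["CHEBI:4167", "MNXR0299", "CHEBI:61548"], [-1, 1])]
        rows = pathway_enzymes(glucokinase_graph, pathways)
        assert rows.to_dict("records") == [{
            "reaction_id": "MNXR0299", "enzyme_id": "P0A6V8",
            "organism_taxonomy": "83333"}]

    def test_empty_pathway_list_gives_empty_table(self, glucokinase_graph):
        assert pathway_enzymes(glucokinase_graph, []).empty

    def test_uncatalysed_reaction_yields_blank_enzyme_row(self):
        g = _chain_graph()
        rows = pathway_enzymes(g, [Pathway(["M", "r2", "T"], [-1, 1])])
        assert rows.to_dict("records") == [{
            "reaction_id": "r2", "enzyme_id": "", "organism_taxonomy": ""}]
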