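"""Namespace mapping, cross-source merging and the build pipeline."""

import pytest

from metabokg.errors import UnmappedNamespaceError
from metabokg.integrate import (
    BuildConfig,
    NamespaceMap,
    build_graph,
    merge_entities,
    normalize_namespace_key,
)
from metabokg.model import ChemicalEntity
from metabokg.source_io import FixtureSpec, generate_fixture


@pytest.mark.parametrize(
    "token,context,expected",
    [
        ("KEGG COMPOUND accession", "Chemical", "kegg.compound"),
        ("chebi", "Chemical", "chebi"),
        ("CHEBI", "Chemical", "chebi"),
        ("kegg", "Reaction", "kegg.reaction"),
        ("kegg", "Chemical", "kegg.compound"),
        ("MNXREF", "Chemical", "mnx"),
        ("seed", "Chemical", "seed.compound"),
        ("seed", "Reaction", "seed"),
        ("rhea", "Reaction", "rhea"),
    ],
)
def test_namespace_normalization(token, context, expected):
    assert normalize_namespace_key(token, context) == expected


def test_unknown_namespace_token_is_an_explicit_error():
    with pytest.raises(UnmappedNamespaceError, match="mystery_db"):
        normalize_namespace_key("mystery_db", "Chemical")


def test_namespace_map_is_extensible():
    nsmap = NamespaceMap({"mystery_db": "chebi"})
    assert nsmap.normalize("MYSTERY_DB", "Chemical") == "chebi"


class TestMergeEntities:
    def test_shared_kegg_xref_merges_chebi_and_mnx_atp(self):
        chebi_atp = ChemicalEntity(
            "CHEBI:15422", "ATP", source="chebi",
            xrefs={"chebi": "CHEBI:15422", "kegg.compound": "C00002"})
        mnx_atp = ChemicalEntity(
            "MNXM3", "ATP", source="mnxref",
            xrefs={"mnx": "MNXM3", "kegg.compound": "C00002"})
        merged, report = merge_entities([chebi_atp, mnx_atp])
        (atp,) = merged
        assert atp.id == "CHEBI:15422"  # chebi outranks mnxref
        assert atp.xrefs == {
            "chebi": "CHEBI:15422", "kegg.compound": "C00002",
            "mnx": "MNXM3",
        }
        assert report.merge_map == {"MNXM3": "CHEBI:15422"}

    def test_disjoint_xrefs_stay_apart(self):
        a = ChemicalEntity("A", xrefs={"chebi": "CHEBI:1"}, source="chebi")
        b = ChemicalEntity("B", xrefs={"mnx": "MNXM2"}, source="mnxref")
        merged, report = merge_entities([a, b])
        assert len(merged) == 2
        assert report.merge_map == {}

    def test_merging_is_transitive_like_union_find(self):
        a = ChemicalEntity("A", source="chebi",
                           xrefs={"chebi": "CHEBI:1", "hmdb": "HMDB1"})
        b = ChemicalEntity("B", source="mnxref",
                           xrefs={"chebi": "CHEBI:1", "mnx": "MNXM1"})
        c = ChemicalEntity("C", source="mnxref",
                           xrefs={"mnx": "MNXM1", "cas": "50-00-0"})
        merged, _ = merge_entities([a, b, c])
        (only,) = merged
        assert set(only.xrefs) == {"chebi", "hmdb", "mnx", "cas"}

    def test_conflicting_scalars_logged_with_winner_kept(self):
        a = ChemicalEntity("A", "alpha", source="chebi", charge=-1,
                           xrefs={"kegg.compound": "C1"})
        b = ChemicalEntity("B", "beta", source="mnxref", charge=-2,
                           xrefs={"kegg.compound": "C1"})
        (m,), report = merge_entities([a, b])
        assert m.charge == -1
        assert "beta" in m.names  # losing name demoted to synonym
        conflict_props = {c[1] for c in report.conflicts}
        assert {"name", "charge"} <= conflict_props

    def test_contradictory_accession_in_second_namespace_still_merges(self):
        a = ChemicalEntity("A", source="chebi",
                           xrefs={"kegg.compound": "C1", "hmdb": "H1"})
        b = ChemicalEntity("B", source="mnxref",
                           xrefs={"kegg.compound": "C1", "hmdb": "H2"})
        merged, report = merge_entities([a, b])
        assert len(merged) == 1
        assert merged[0].xrefs["hmdb"] == "H1"
        assert any(c[1] == "xref:hmdb" for c in report.conflicts)

    def test_merge_is_idempotent(self):
        entities = [
            ChemicalEntity("A", source="chebi",
                           xrefs={"chebi": "CHEBI:1", "mnx": "MNXM1"}),
            ChemicalEntity("B", source="mnxref", xrefs={"mnx": "MNXM1"}),
            ChemicalEntity("C", source="mnxref", xrefs={"mnx": "MNXM9"}),
        ]
        once, _ = merge_entities(entities)
        twice, report = merge_entities(once)
        assert [e.id for e in twice] == [e.id for e in once]
        assert report.merge_map == {}


class TestBuildGraph:
    def test_counts_match_generator_ground_truth(self, built):
        graph, _, _, truth = built
        assert graph.n_nodes("Organism") == truth.n_organisms
        assert graph.n_nodes("Enzyme") == truth.n_enzymes
        assert graph.n_nodes("Reaction") == truth.n_reactions
        assert graph.n_nodes("Chemical") == truth.n_chemicals
        taxonomy_edges = sum(
            1 for r in graph.relationships
            if r.type == "is_a" and graph.label_of(r.from_id) == "Organism"
        )
        ontology_edges = sum(
            1 for r in graph.relationships
            if graph.label_of(r.from_id) == "Chemical"
        )
        assert taxonomy_edges == truth.n_taxonomy_edges
        assert ontology_edges == truth.n_chemical_relations
        assert graph.n_relationships("expresses") == truth.n_expresses
        assert graph.n_relationships("catalysed_by") == truth.n_catalysed_by
        n_participant_edges = sum(
            len(r.participants) for r in graph.nodes["Reaction"].values()
        )
        assert (graph.n_relationships("has_reactant")
                + graph.n_relationships("has_cofactor")
                ) == n_participant_edges

    def test_full_sharing_collapses_to_n_chemicals(self, tmp_path):
        spec = FixtureSpec(n_chemicals=12, fraction_shared_xrefs=1.0, seed=3)
        truth = generate_fixture(spec, tmp_path)
        graph, report, _ = build_graph(tmp_path)
        assert graph.n_nodes("Chemical") == truth.n_chemicals == 12
        assert len(report.merge_map) == 12

    def test_post_merge_xref_uniqueness(self, built):
        graph = built[0]
        seen = {}
        for chem in graph.nodes["Chemical"].values():
            for pair in chem.xrefs.items():
                assert pair not in seen, f"{pair} on two chemicals"
                seen[pair] = chem.id

    def test_rewired_edges_have_no_dangling_endpoints(self, built):
        built[0].check_integrity()

    def test_empty_source_dir_builds_empty_graph(self, tmp_path):
        graph, _, log = build_graph(tmp_path)
        assert graph.n_nodes() == 0
        assert any("missing source file" in line for line in log)

    def test_merge_report_exports_csv(self, built, tmp_path):
        _, report, _, _ = built
        report.to_csv(tmp_path / "conflicts.csv")
        assert (tmp_path / "conflicts.csv").exists()


def test_build_config_from_yaml(tmp_path):
    cfg_file = tmp_path / "config.yaml"
    cfg_file.write_text(
        "namespace_map:\n  localdb: chebi\n"
        "cofactor:\n  min_pair_count: 3\n"
        "balance:\n  max_coefficient: 10\n"
        "pathway:\n  max_len: 5\n"
    )
    cfg = BuildConfig.from_yaml(cfg_file)
    assert cfg.namespace_map == {"localdb": "chebi"}
    assert cfg.cofactor_min_pair_count == 3
    assert cfg.balance_max_coefficient == 10
    assert cfg.pathway_max_len == 5
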