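"""Flat-file dialect parsing and fixture generation round trips."""

import pytest

from metabokg.errors import FixtureSpecError, ParseError
from metabokg.source_io import (
    CHEBI_COMPOUNDS,
    CHEBI_DATA,
    CHEBI_NAMES,
    CHEBI_RELATIONS,
    FixtureSpec,
    generate_fixture,
    parse_chebi_ontology,
    parse_mnxref_chemicals,
    parse_mnxref_reactions,
    parse_protein_table,
    parse_reaction_equation,
    parse_taxonomy_dump,
)

NODES_3 = (
    "1\t|\t1\t|\tno rank\t|\n"
    "562\t|\t1\t|\tspecies\t|\n"
    "83333\t|\t562\t|\tstrain\t|\n"
)
NAMES_3 = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "562\t|\tEscherichia coli\t|\t\t|\tscientific name\t|\n"
    "562\t|\tBacillus coli Migula 1895\t|\t\t|\tsynonym\t|\n"
    "83333\t|\tEscherichia coli K-12\t|\t\t|\tscientific name\t|\n"
)


def test_taxonomy_three_line_dump(tmp_path):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    nodes.write_text(NODES_3)
    names.write_text(NAMES_3)
    organisms, rels = parse_taxonomy_dump(nodes, names)
    assert len(organisms) == 3
    # root has no self is_a edge
    assert len(rels) == 2
    assert {(r.from_id, r.to_id) for r in rels} == {("562", "1"),
                                                    ("83333", "562")}
    by_id = {o.taxonomy: o for o in organisms}
    assert by_id["562"].name == "Escherichia coli"
    assert by_id["562"].names == ["Bacillus coli Migula 1895"]
    assert by_id["1"].parent_taxonomy is None


def test_taxonomy_unknown_name_reference_is_skipped(tmp_path, caplog):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    nodes.write_text("1\t|\t1\t|\tno rank\t|\n")
    names.write_text("99\t|\tghost\t|\t\t|\tscientific name\t|\n")
    organisms, _ = parse_taxonomy_dump(nodes, names)
    assert len(organisms) == 1


def test_taxonomy_malformed_line_reports_line_number(tmp_path):
    nodes = tmp_path / "nodes.dmp"
    nodes.write_text("1\t|\t1\t|\tno rank\t|\nbroken line\n")
    (tmp_path / "names.dmp").write_text("")
    with pytest.raises(ParseError, match="2"):
        parse_taxonomy_dump(nodes, tmp_path / "names.dmp")


def test_mnx_chemical_row_with_xref(tmp_path):
    f = tmp_path / "chem_prop.tsv"
    f.write_text(
        "# header\n"
        "MNXM3\tATP\tC10H12N5O13P3\t-4\t506.9957\tInChI=1S/x\tOC1\t"
        "chebi:15422\n"
    )
    (chem,) = parse_mnxref_chemicals(f)
    assert chem.xrefs == {"mnx": "MNXM3", "chebi": "CHEBI:15422"}
    assert chem.charge == -4
    assert chem.monoisotopic_mass == pytest.approx(506.9957)


def test_mnx_chemical_degenerate_cells(tmp_path, caplog):
    f = tmp_path / "chem_prop.tsv"
    f.write_text("MNXM9\tmystery\t\tn/a\t\t\t\t\n")
    (chem,) = parse_mnxref_chemicals(f)
    assert chem.formula is None
    assert chem.charge is None
    assert "charge" in caplog.text


def test_mnx_duplicate_chemical_id_is_an_error(tmp_path):
    f = tmp_path / "chem_prop.tsv"
    f.write_text("MNXM1\ta\t\t\t\t\t\t\nMNXM1\tb\t\t\t\t\t\t\n")
    with pytest.raises(ParseError, match="duplicate"):
        parse_mnxref_chemicals(f)


@pytest.mark.parametrize(
    "equation,expected",
    [
        ("1 G + 1 ATP = 1 G6P + 1 ADP",
         [("G", -1), ("ATP", -1), ("G6P", 1), ("ADP", 1)]),
        ("2 A = 1 B", [("A", -2), ("B", 1)]),
        ("A + B = C", [("A", -1), ("B", -1), ("C", 1)]),
        ("1 A = 1 A", []),              # degenerate: cancels out
        ("1 A = 2 A", [("A", 1)]),      # unequal sides net
    ],
)
def test_equation_grammar(equation, expected):
    parts = parse_reaction_equation(equation, "r")
    assert [(p.chemical_id, p.stoichiometry) for p in parts] == expected


def test_equation_without_equals_is_an_error():
    with pytest.raises(ParseError):
        parse_reaction_equation("1 A + 1 B", "rX")


def test_mnx_reactions_parse(tmp_path):
    f = tmp_path / "reac_prop.tsv"
    f.write_text(
        "# id\tequation\tec\tbalance\txref\n"
        "MNXR1\t1 MNXM_glc + 1 MNXM_atp = 1 MNXM_g6p + 1 MNXM_adp\t"
        "2.7.1.1;2.7.1.2\ttrue\tkegg.reaction:R00299\n"
        "MNXR2\t1 A = 1 B\t\t\t\n"
    )
    r1, r2 = parse_mnxref_reactions(f)
    assert [p.stoichiometry for p in r1.participants] == [-1, -1, 1, 1]
    assert r1.ec == ["2.7.1.1", "2.7.1.2"]
    assert r1.balance is True
    assert r1.xrefs["kegg.reaction"] == "R00299"
    assert r2.balance is None


def test_chebi_ontology_parse(tmp_path, caplog):
    (tmp_path / CHEBI_COMPOUNDS).write_text(
        "CHEBI:47916\tflavonoid\nCHEBI:1\tflavone\nCHEBI:2\tapigenin\n")
    (tmp_path / CHEBI_RELATIONS).write_text(
        "is_a\tCHEBI:1\tCHEBI:47916\n"
        "has_functional_parent\tCHEBI:2\tCHEBI:1\n"
        "made_up_relation\tCHEBI:2\tCHEBI:1\n"
        "is_a\tCHEBI:99\tCHEBI:1\n"
    )
    (tmp_path / CHEBI_DATA).write_text(
        "CHEBI:2\tFORMULA\tC15H10O5\nCHEBI:2\tCHARGE\t0\n"
        "CHEBI:47916\tFORMULA\t\n"
    )
    (tmp_path / CHEBI_NAMES).write_text("CHEBI:2\t4',5,7-trihydroxyflavone\n")
    chems, rels = parse_chebi_ontology(
        tmp_path / CHEBI_COMPOUNDS, tmp_path / CHEBI_RELATIONS,
        tmp_path / CHEBI_DATA, tmp_path / CHEBI_NAMES)
    by_id = {c.id: c for c in chems}
    assert by_id["CHEBI:47916"].formula is None  # class node, still valid
    assert by_id["CHEBI:2"].formula == "C15H10O5"
    assert by_id["CHEBI:2"].names == ["4',5,7-trihydroxyflavone"]
    # unknown type and unknown id rows were dropped
    assert {(r.from_id, r.to_id, r.type) for r in rels} == {
        ("CHEBI:1", "CHEBI:47916", "is_a"),
        ("CHEBI:2", "CHEBI:1", "has_functional_parent"),
    }


def test_protein_table_resolution_and_dedup(tmp_path):
    f = tmp_path / "proteins.tsv"
    f.write_text(
        "P0A6V8\tGLK_ECOLI\tGlucokinase\t\t2.7.1.2\t83333\t"
        "kegg:R00299\n"
        "P0A6V8\tGLK_ECOLI\tGlucokinase\t\t2.7.1.2\t511145\t\n"
        "P11111\tX_Y\tother\t\t\t562\tkegg:R99999\n"
    )
    index = {("kegg.reaction", "R00299"): "MNXR0299"}
    enzymes, expresses, catalysed_by, deferred = parse_protein_table(f, index)
    assert len(enzymes) == 1 + 1  # same uniprot rows collapse to one node
    assert len(expresses) == 3
    (cat,) = catalysed_by
    assert (cat.from_id, cat.to_id) == ("MNXR0299", "P0A6V8")
    assert cat.props["source"] == "kegg.reaction"
    (d,) = deferred
    assert (d.namespace, d.accession) == ("kegg.reaction", "R99999")


class TestFixtureGenerator:
    def test_same_seed_gives_byte_identical_directories(self, tmp_path):
        spec = FixtureSpec(seed=42)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        t1 = generate_fixture(spec, d1)
        t2 = generate_fixture(spec, d2)
        assert t1 == t2
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes()

    def test_taxonomy_ground_truth(self, tmp_path):
        spec = FixtureSpec(n_organisms=10, tree_depth=3, seed=0)
        truth = generate_fixture(spec, tmp_path)
        organisms, rels = parse_taxonomy_dump(
            tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert len(organisms) == truth.n_organisms == 10
        assert len(rels) == truth.n_taxonomy_edges == 9

    def test_shared_xref_count(self, tmp_path):
        spec = FixtureSpec(n_chemicals=10, fraction_shared_xrefs=0.5, seed=0)
        truth = generate_fixture(spec, tmp_path)
        assert len(truth.shared_pairs) == 5
        chems = parse_mnxref_chemicals(tmp_path / "chem_prop.tsv")
        chebi_linked = [c for c in chems if "chebi" in c.xrefs]
        assert len(chebi_linked) == 5

    def test_parser_counts_match_ground_truth(self, fixture_dir):
        src, truth = fixture_dir
        chems = parse_mnxref_chemicals(src / "chem_prop.tsv")
        rxns = parse_mnxref_reactions(src / "reac_prop.tsv")
        assert len(chems) == truth.n_chemicals  # pre-merge: all in MNX file
        assert len(rxns) == truth.n_reactions

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_organisms": 0},
            {"fraction_unbalanced": 1.5},
            {"n_chemicals": 2, "fraction_unbalanced": 0.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, tmp_path):
        with pytest.raises(FixtureSpecError):
            generate_fixture(FixtureSpec(**kwargs), tmp_path)


def test_parsers_tolerate_crlf_and_blank_lines(tmp_path):
    f = tmp_path / "chem_prop.tsv"
    f.write_bytes(b"# comment\r\nMNXM1\twater\tH2O\t0\t\t\t\t\r\n\r\n")
    (chem,) = parse_mnxref_chemicals(f)
    assert chem.formula == "H2O"
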