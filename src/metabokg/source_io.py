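"""Flat-file parsers for miniature source dumps, plus a synthetic-fixture
generator with known ground truth.

Supported dialects (frozen, documented here; real releases vary by version):

* NCBI-taxonomy-style ``nodes.dmp`` / ``names.dmp``: fields separated by
  ``\\t|\\t``, lines terminated ``\\t|``.
* MNXref-style ``chem_prop.tsv`` / ``reac_prop.tsv``: tab-separated with
  ``#``-prefixed comment headers; reaction equations in
  ``coef id (+ coef id)* = coef id (+ coef id)*`` form.
* ChEBI-style four-table ontology dump: ``chebi_compounds.tsv``,
  ``chebi_relations.tsv``, ``chebi_data.tsv``, ``chebi_names.tsv``.
* A UniProt-like ``proteins.tsv`` with per-protein taxon and reaction links.

All readers accept LF and CRLF, skip comment and blank lines, and are
deterministic: the same bytes yield the same entity order.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .errors import FixtureSpecError, ParseError
from .integrate import normalize_xref
from .model import (
    CHEMICAL_RELATION_TYPES,
    ChemicalEntity,
    EnzymeEntity,
    OrganismEntity,
    Participant,
    ReactionEntity,
    Relationship,
)

logger = logging.getLogger(__name__)

# conventional file names inside a source directory
TAXONOMY_NODES = "nodes.dmp"
TAXONOMY_NAMES = "names.dmp"
MNX_CHEMICALS = "chem_prop.tsv"
MNX_REACTIONS = "reac_prop.tsv"
CHEBI_COMPOUNDS = "chebi_compounds.tsv"
CHEBI_RELATIONS = "chebi_relations.tsv"
CHEBI_DATA = "chebi_data.tsv"
CHEBI_NAMES = "chebi_names.tsv"
PROTEINS = "proteins.tsv"

SOURCE_FILES = (
    TAXONOMY_NODES, TAXONOMY_NAMES, MNX_CHEMICALS, MNX_REACTIONS,
    CHEBI_COMPOUNDS, CHEBI_RELATIONS, CHEBI_DATA, CHEBI_NAMES, PROTEINS,
)


def _read_lines(path: Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").split("\n")


def _dmp_fields(line: str) -> list[str]:
    line = line.rstrip()
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


# ---------------------------------------------------------------------------
# NCBI taxonomy
# ---------------------------------------------------------------------------

def parse_taxonomy_dump(
    nodes_file: Path, names_file: Path
) -> tuple[list[OrganismEntity], list[Relationship]]:
    """Parse nodes.dmp/names.dmp into organisms plus child->parent ``is_a``
    edges.

    The root (tax_id == parent_tax_id) gets no self-edge.  The ``scientific
    name`` class populates ``name``; every other name class goes to
    ``names``.  A names.dmp tax_id absent from nodes.dmp is skipped with a
    warning.
    """
    organisms: dict[str, OrganismEntity] = {}
    rels: list[Relationship] = []
    for lineno, raw in enumerate(_read_lines(nodes_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = _dmp_fields(raw)
        if len(fields) < 2:
            raise ParseError("nodes.dmp line has fewer than 2 fields",
                             nodes_file, lineno)
        tax_id, parent_id = fields[0].strip(), fields[1].strip()
        if not tax_id:
            raise ParseError("empty tax_id", nodes_file, lineno)
        org = OrganismEntity(taxonomy=tax_id)
        if tax_id != parent_id:
            org.parent_taxonomy = parent_id
            rels.append(Relationship.make(tax_id, parent_id, "is_a"))
        organisms[tax_id] = org
    for lineno, raw in enumerate(_read_lines(names_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = _dmp_fields(raw)
        if len(fields) < 4:
            raise ParseError("names.dmp line has fewer than 4 fields",
                             names_file, lineno)
        tax_id, name_txt, _unique, name_class = (f.strip() for f in fields[:4])
        org = organisms.get(tax_id)
        if org is None:
            logger.warning("names.dmp references unknown tax_id %s (line %d)",
                           tax_id, lineno)
            continue
        if name_class == "scientific name" and not org.name:
            org.name = name_txt
        elif name_txt and name_txt not in org.names:
            org.names.append(name_txt)
    return list(organisms.values()), rels


# ---------------------------------------------------------------------------
# MNXref
# ---------------------------------------------------------------------------

def parse_mnxref_chemicals(chem_prop_file: Path) -> list[ChemicalEntity]:
    """Parse an MNXref-style chemical property TSV.

    Columns: id, name, formula, charge, mass, inchi, smiles, xref.  The xref
    cell holds ';'-joined ``namespace:accession`` tokens in source-local
    namespace spelling; tokens are normalised to identifiers.org keys.
    Empty cells leave the corresponding field unset.
    """
    chemicals: list[ChemicalEntity] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(_read_lines(chem_prop_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 8:
            cols += [""] * (8 - len(cols))
        cid, name, formula, charge_s, mass_s, inchi, smiles, xref_s = (
            c.strip() for c in cols[:8]
        )
        if not cid:
            raise ParseError("empty chemical id", chem_prop_file, lineno)
        if cid in seen:
            raise ParseError(f"duplicate chemical id {cid!r}",
                             chem_prop_file, lineno)
        seen.add(cid)
        chem = ChemicalEntity(id=cid, name=name, source="mnxref")
        if formula:
            chem.formula = formula
        if charge_s:
            try:
                chem.charge = int(charge_s)
            except ValueError:
                logger.warning(
                    "non-integer charge %r for %s dropped (line %d)",
                    charge_s, cid, lineno,
                )
        if mass_s:
            try:
                chem.monoisotopic_mass = float(mass_s)
            except ValueError:
                logger.warning("non-numeric mass %r for %s dropped", mass_s,
                               cid)
        if inchi:
            chem.inchi = inchi
        if smiles:
            chem.smiles = smiles
        ns, acc = normalize_xref("mnx", cid, "Chemical")
        chem.xrefs[ns] = acc
        for token in filter(None, (t.strip() for t in xref_s.split(";"))):
            if ":" not in token:
                logger.warning("malformed xref %r for %s skipped", token, cid)
                continue
            raw_ns, raw_acc = token.split(":", 1)
            ns, acc = normalize_xref(raw_ns, raw_acc, "Chemical")
            chem.xrefs.setdefault(ns, acc)
        chemicals.append(chem)
    return chemicals


def parse_reaction_equation(
    equation: str, reaction_id: str = ""
) -> list[Participant]:
    """Parse ``coef id (+ coef id)* = coef id (+ coef id)*`` into signed
    participants: left side negative, right side positive; omitted
    coefficients default to 1.  A chemical on both sides is netted (equal
    coefficients cancel to nothing, with a warning)."""
    if "=" not in equation:
        raise ParseError(
            f"equation for reaction {reaction_id!r} lacks '=': {equation!r}"
        )
    left_s, right_s = equation.split("=", 1)
    net: dict[str, int] = {}
    order: list[str] = []
    for side_s, sign in ((left_s, -1), (right_s, +1)):
        side_s = side_s.strip()
        if not side_s:
            continue
        for term in side_s.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 1:
                coef, cid = 1, bits[0]
            elif len(bits) == 2:
                try:
                    coef = int(bits[0])
                except ValueError:
                    raise ParseError(
                        f"bad coefficient {bits[0]!r} in reaction "
                        f"{reaction_id!r}"
                    ) from None
                cid = bits[1]
            else:
                raise ParseError(
                    f"unparseable term {term!r} in reaction {reaction_id!r}"
                )
            if coef <= 0:
                raise ParseError(
                    f"non-positive coefficient in reaction {reaction_id!r}"
                )
            if cid not in net:
                net[cid] = 0
                order.append(cid)
            net[cid] += sign * coef
    participants = []
    for cid in order:
        if net[cid] == 0:
            logger.warning(
                "chemical %s cancels out of reaction %s", cid, reaction_id
            )
            continue
        participants.append(Participant(cid, net[cid]))
    return participants


_BALANCE_FLAGS = {"true": True, "false": False, "unknown": None, "": None,
                  "1": True, "0": False, "nr": None, "ambiguous": None}


def parse_mnxref_reactions(reac_prop_file: Path) -> list[ReactionEntity]:
    """Parse an MNXref-style reaction property TSV.

    Columns: id, equation, ec (';'-joined), balance, xref.  Left-hand
    participants get negative stoichiometry, right-hand positive; the
    balance column maps onto the tri-state flag.
    """
    reactions: list[ReactionEntity] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(_read_lines(reac_prop_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 5:
            cols += [""] * (5 - len(cols))
        rid, equation, ec_s, balance_s, xref_s = (c.strip() for c in cols[:5])
        if not rid:
            raise ParseError("empty reaction id", reac_prop_file, lineno)
        if rid in seen:
            raise ParseError(f"duplicate reaction id {rid!r}",
                             reac_prop_file, lineno)
        seen.add(rid)
        rxn = ReactionEntity(id=rid, source="mnxref")
        rxn.participants = parse_reaction_equation(equation, rid)
        if ec_s:
            rxn.ec = [e.strip() for e in ec_s.split(";") if e.strip()]
        if balance_s.lower() not in _BALANCE_FLAGS:
            logger.warning("unknown balance flag %r for %s", balance_s, rid)
        rxn.balance = _BALANCE_FLAGS.get(balance_s.lower())
        ns, acc = normalize_xref("mnx", rid, "Reaction")
        rxn.xrefs[ns] = acc
        for token in filter(None, (t.strip() for t in xref_s.split(";"))):
            if ":" not in token:
                logger.warning("malformed xref %r for %s skipped", token, rid)
                continue
            raw_ns, raw_acc = token.split(":", 1)
            ns, acc = normalize_xref(raw_ns, raw_acc, "Reaction")
            rxn.xrefs.setdefault(ns, acc)
        reactions.append(rxn)
    return reactions


# ---------------------------------------------------------------------------
# ChEBI ontology
# ---------------------------------------------------------------------------

def parse_chebi_ontology(
    compounds_file: Path,
    relations_file: Path,
    data_file: Path,
    names_file: Path,
) -> tuple[list[ChemicalEntity], list[Relationship]]:
    """Parse the simplified four-table chemical-ontology dump.

    compounds: (chebi_id, name); relations: (type, child, parent) with the
    nine chemical relation types, direction stored child->parent; data:
    (chebi_id, key in {FORMULA, CHARGE, MONOISOTOPIC MASS}, value); names:
    (chebi_id, synonym).  Unknown relation types or chebi ids are skipped
    with a warning.  Class nodes without formula/mass are kept.
    """
    chems: dict[str, ChemicalEntity] = {}
    for lineno, raw in enumerate(_read_lines(compounds_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise ParseError("compounds line needs (chebi_id, name)",
                             compounds_file, lineno)
        cid, name = cols[0].strip(), cols[1].strip()
        ns, acc = normalize_xref("chebi", cid, "Chemical")
        chem = ChemicalEntity(id=acc, name=name, source="chebi")
        chem.xrefs[ns] = acc
        chems[acc] = chem
    for lineno, raw in enumerate(_read_lines(data_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 3:
            cols += [""] * (3 - len(cols))
        cid, key, value = (c.strip() for c in cols[:3])
        _, acc = normalize_xref("chebi", cid, "Chemical")
        chem = chems.get(acc)
        if chem is None:
            logger.warning("data row for unknown chebi id %s skipped", cid)
            continue
        if not value:
            continue
        if key == "FORMULA":
            chem.formula = value
        elif key == "CHARGE":
            try:
                chem.charge = int(value)
            except ValueError:
                logger.warning("non-integer CHARGE %r for %s dropped",
                               value, cid)
        elif key == "MONOISOTOPIC MASS":
            try:
                chem.monoisotopic_mass = float(value)
            except ValueError:
                logger.warning("bad MONOISOTOPIC MASS %r for %s dropped",
                               value, cid)
        else:
            logger.warning("unknown data key %r for %s skipped", key, cid)
    for lineno, raw in enumerate(_read_lines(names_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            continue
        cid, synonym = cols[0].strip(), cols[1].strip()
        _, acc = normalize_xref("chebi", cid, "Chemical")
        chem = chems.get(acc)
        if chem is None:
            logger.warning("synonym for unknown chebi id %s skipped", cid)
            continue
        if synonym and synonym not in chem.names:
            chem.names.append(synonym)
    rels: list[Relationship] = []
    for lineno, raw in enumerate(_read_lines(relations_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 3:
            raise ParseError("relations line needs (type, child, parent)",
                             relations_file, lineno)
        rtype, child, parent = (c.strip() for c in cols[:3])
        if rtype not in CHEMICAL_RELATION_TYPES:
            logger.warning("relation type %r outside the ontology set "
                           "skipped (line %d)", rtype, lineno)
            continue
        _, child_acc = normalize_xref("chebi", child, "Chemical")
        _, parent_acc = normalize_xref("chebi", parent, "Chemical")
        if child_acc not in chems or parent_acc not in chems:
            logger.warning("relation references unknown chebi id "
                           "(%s, %s) skipped", child, parent)
            continue
        rels.append(Relationship.make(child_acc, parent_acc, rtype))
    return list(chems.values()), rels


# ---------------------------------------------------------------------------
# UniProt-like protein table
# ---------------------------------------------------------------------------

@dataclass
class DeferredReactionLink:
    """A Reaction->Enzyme link that could not be resolved at parse time."""

    uniprot: str
    namespace: str
    accession: str


def parse_protein_table(
    protein_file: Path,
    reaction_index: Optional[Mapping[tuple[str, str], str]] = None,
) -> tuple[
    list[EnzymeEntity],
    list[Relationship],
    list[Relationship],
    list[DeferredReactionLink],
]:
    """Parse the protein TSV into enzymes, ``expresses`` edges and
    ``catalysed_by`` edges.

    Columns: uniprot, entry, name, synonyms (';'-joined), ec (';'-joined),
    taxonomy_id, reaction_xrefs (';'-joined ``namespace:accession``).
    Reaction xrefs are resolved against ``reaction_index`` — a map from
    normalised (namespace, accession) to reaction node key; unresolved links
    are returned for the caller to retry once all reactions are loaded.
    Rows sharing a uniprot id describe one enzyme expressed by several taxa.
    """
    enzymes: dict[str, EnzymeEntity] = {}
    expresses: list[Relationship] = []
    catalysed_by: list[Relationship] = []
    deferred: list[DeferredReactionLink] = []
    reaction_index = reaction_index or {}
    seen_links: set[tuple[str, str, str]] = set()
    for lineno, raw in enumerate(_read_lines(protein_file), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 7:
            cols += [""] * (7 - len(cols))
        uniprot, entry, name, syn_s, ec_s, taxonomy_id, rx_s = (
            c.strip() for c in cols[:7]
        )
        if not uniprot:
            raise ParseError("empty uniprot accession", protein_file, lineno)
        enz = enzymes.get(uniprot)
        if enz is None:
            enz = EnzymeEntity(uniprot=uniprot, entry=entry, name=name)
            enz.names = [s.strip() for s in syn_s.split(";") if s.strip()]
            enz.ec_code = [e.strip() for e in ec_s.split(";") if e.strip()]
            enzymes[uniprot] = enz
        elif name and not enz.name:
            enz.name = name
        if taxonomy_id:
            expresses.append(
                Relationship.make(taxonomy_id, uniprot, "expresses",
                                  source="uniprot")
            )
        for token in filter(None, (t.strip() for t in rx_s.split(";"))):
            if ":" not in token:
                logger.warning("malformed reaction xref %r for %s skipped",
                               token, uniprot)
                continue
            raw_ns, raw_acc = token.split(":", 1)
            ns, acc = normalize_xref(raw_ns, raw_acc, "Reaction")
            rxn_id = reaction_index.get((ns, acc))
            if rxn_id is None:
                deferred.append(DeferredReactionLink(uniprot, ns, acc))
            elif (rxn_id, uniprot, ns) not in seen_links:
                seen_links.add((rxn_id, uniprot, ns))
                catalysed_by.append(
                    Relationship.make(rxn_id, uniprot, "catalysed_by",
                                      source=ns)
                )
    return list(enzymes.values()), expresses, catalysed_by, deferred


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters of the synthetic source-file bundle.

    Defaults describe a miniature but structurally complete knowledge
    graph: a 50-taxon tree, 30 enzymes, 20 hydration-style reactions over
    40 chemicals, a quarter of the reactions deliberately proton-stripped
    and a quarter of the chemicals present in two sources.
    """

    n_organisms: int = 50
    tree_depth: int = 4
    n_enzymes: int = 30
    n_reactions: int = 20
    n_chemicals: int = 40
    fraction_unbalanced: float = 0.25
    fraction_shared_xrefs: float = 0.25
    seed: int = 42

    def validate(self) -> None:
        for f in ("n_organisms", "tree_depth", "n_enzymes", "n_reactions",
                  "n_chemicals"):
            if getattr(self, f) < 1:
                raise FixtureSpecError(f"{f} must be >= 1")
        for f in ("fraction_unbalanced", "fraction_shared_xrefs"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{f} must lie in [0, 1]")
        if self.n_chemicals < 3 and self.fraction_unbalanced > 0:
            raise FixtureSpecError(
                "fraction_unbalanced > 0 requires n_chemicals >= 3 "
                "(proton, substrate and product)"
            )
        if self.n_chemicals < 4:
            raise FixtureSpecError(
                "the generator needs n_chemicals >= 4: proton, water and at "
                "least one substrate/product pair"
            )


@dataclass
class FixtureGroundTruth:
    """What build_graph on the generated files must produce."""

    n_organisms: int
    n_taxonomy_edges: int
    n_enzymes: int
    n_expresses: int
    n_catalysed_by: int
    n_reactions: int
    n_chemicals: int
    n_chemical_relations: int
    #: reaction id -> pre-corruption participants [(canonical chem id, stoich)]
    unbalanced: dict[str, list[tuple[str, int]]]
    #: (mnx id, chebi id) pairs emitted in both sources
    shared_pairs: list[tuple[str, str]]
    #: mnx chemical id -> canonical (post-merge) node key
    canonical_of: dict[str, str]
    proton_id: str = ""
    water_id: str = ""


def generate_fixture(spec: FixtureSpec, out_dir: Path) -> FixtureGroundTruth:
    """Write the five source-file dialects with known ground truth.

    Chemistry scheme: chemical 0 is a proton (H, +1), chemical 1 water
    (H2O, 0); the rest form substrate/product pairs (CkH2kOk, CkH2k+1Ok+1
    with charge -1).  Every reaction is a hydration with proton release,
    ``1 A + 1 H2O = 1 P + 1 H+``, exactly balanced by construction.  The
    first ``round(fraction_unbalanced * n_reactions)`` reactions are written
    with the proton stripped; ground truth records their true stoichiometries.
    The first ``round(fraction_shared_xrefs * n_chemicals)`` chemicals are
    emitted in both the MNXref and ChEBI files under linked cross-references.
    Deterministic: the same spec (including seed) gives byte-identical files.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ---- chemicals -------------------------------------------------------
    n = spec.n_chemicals
    mnx_ids = [f"MNXM{i:04d}" for i in range(n)]
    formulas: list[str] = []
    charges: list[int] = []
    names: list[str] = []
    for i in range(n):
        if i == 0:
            formulas.append("H"); charges.append(1); names.append("proton")
        elif i == 1:
            formulas.append("H2O"); charges.append(0); names.append("water")
        else:
            j = i - 2
            k = 3 + j // 2
            if j % 2 == 0:  # substrate
                formulas.append(f"C{k}H{2 * k}O{k}")
                charges.append(0)
                names.append(f"substrate-{k}")
            else:           # product anion of the preceding substrate
                formulas.append(f"C{k}H{2 * k + 1}O{k + 1}")
                charges.append(-1)
                names.append(f"product-{k}(1-)")

    n_shared = round(spec.fraction_shared_xrefs * n)
    shared_idx = list(range(n_shared))
    chebi_acc = {i: f"CHEBI:{10000 + i}" for i in shared_idx}
    shared_pairs = [(mnx_ids[i], chebi_acc[i]) for i in shared_idx]
    # chebi outranks mnxref, so shared chemicals keep the ChEBI key
    canonical_of = {
        mnx_ids[i]: chebi_acc.get(i, mnx_ids[i]) for i in range(n)
    }

    from .chem import monoisotopic_mass, parse_formula  # local: no cycle

    chem_rows = []
    for i in range(n):
        mass = monoisotopic_mass(parse_formula(formulas[i]))
        xref = f"chebi:{chebi_acc[i].split(':')[1]}" if i in chebi_acc else ""
        chem_rows.append(
            f"{mnx_ids[i]}\t{names[i]}\t{formulas[i]}\t{charges[i]}"
            f"\t{mass:.4f}\t\t\t{xref}"
        )
    _write(out_dir / MNX_CHEMICALS,
           ["# id\tname\tformula\tcharge\tmass\tinchi\tsmiles\txref"]
           + chem_rows)

    chebi_compound_rows, chebi_data_rows, chebi_name_rows = [], [], []
    for i in shared_idx:
        acc = chebi_acc[i]
        chebi_compound_rows.append(f"{acc}\t{names[i]}")
        chebi_data_rows.append(f"{acc}\tFORMULA\t{formulas[i]}")
        chebi_data_rows.append(f"{acc}\tCHARGE\t{charges[i]}")
        mass = monoisotopic_mass(parse_formula(formulas[i]))
        chebi_data_rows.append(f"{acc}\tMONOISOTOPIC MASS\t{mass:.4f}")
        if rng.random() < 0.5:
            chebi_name_rows.append(f"{acc}\tsyn-{names[i]}")
    chebi_rel_rows = []
    rel_cycle = ("is_a", "has_functional_parent", "is_conjugate_base_of")
    for pos in range(1, len(shared_idx)):
        child, parent = chebi_acc[shared_idx[pos]], chebi_acc[shared_idx[pos - 1]]
        chebi_rel_rows.append(
            f"{rel_cycle[pos % len(rel_cycle)]}\t{child}\t{parent}"
        )
    _write(out_dir / CHEBI_COMPOUNDS,
           ["# chebi_id\tname"] + chebi_compound_rows)
    _write(out_dir / CHEBI_DATA, ["# chebi_id\tkey\tvalue"] + chebi_data_rows)
    _write(out_dir / CHEBI_NAMES,
           ["# chebi_id\tsynonym"] + chebi_name_rows)
    _write(out_dir / CHEBI_RELATIONS,
           ["# type\tchild\tparent"] + chebi_rel_rows)

    # ---- reactions -------------------------------------------------------
    n_pairs = (n - 2) // 2
    rxn_ids = [f"MNXR{j:04d}" for j in range(spec.n_reactions)]
    n_unbal = round(spec.fraction_unbalanced * spec.n_reactions)
    unbalanced: dict[str, list[tuple[str, int]]] = {}
    reac_rows = []
    proton, water = mnx_ids[0], mnx_ids[1]
    for j, rid in enumerate(rxn_ids):
        t = j % n_pairs
        a, p = mnx_ids[2 + 2 * t], mnx_ids[3 + 2 * t]
        full = [(a, -1), (water, -1), (p, +1), (proton, +1)]
        if j < n_unbal:
            equation = f"1 {a} + 1 {water} = 1 {p}"
            unbalanced[rid] = [(canonical_of[c], s) for c, s in full]
            flag = "false"
        else:
            equation = f"1 {a} + 1 {water} = 1 {p} + 1 {proton}"
            flag = "true"
        kegg = f"kegg.reaction:R{j + 1:05d}"
        reac_rows.append(f"{rid}\t{equation}\t2.7.1.{j + 1}\t{flag}\t{kegg}")
    _write(out_dir / MNX_REACTIONS,
           ["# id\tequation\tec\tbalance\txref"] + reac_rows)

    # ---- taxonomy --------------------------------------------------------
    n_org = spec.n_organisms
    parents: dict[int, int] = {}
    depth = {1: 0}
    # a root chain down to tree_depth, then round-robin attachment at
    # depths < tree_depth
    attach_points = [1]
    for i in range(2, n_org + 1):
        if i - 1 <= spec.tree_depth:
            parent = i - 1
        else:
            candidates = [t for t in attach_points
                          if depth[t] < spec.tree_depth]
            parent = candidates[(i - 2) % len(candidates)]
        parents[i] = parent
        depth[i] = depth[parent] + 1
        attach_points.append(i)
    node_rows = ["1\t|\t1\t|\tno rank\t|"]
    name_rows = ["1\t|\troot\t|\t\t|\tscientific name\t|"]
    for i in range(2, n_org + 1):
        rank = "species" if depth[i] >= spec.tree_depth else "genus"
        node_rows.append(f"{i}\t|\t{parents[i]}\t|\t{rank}\t|")
        name_rows.append(f"{i}\t|\ttaxon {i}\t|\t\t|\tscientific name\t|")
        if rng.random() < 0.3:
            name_rows.append(f"{i}\t|\ttaxon-{i} legacy\t|\t\t|\tsynonym\t|")
    _write(out_dir / TAXONOMY_NODES, node_rows)
    _write(out_dir / TAXONOMY_NAMES, name_rows)

    # ---- proteins --------------------------------------------------------
    protein_rows = ["# uniprot\tentry\tname\tsynonyms\tec\ttaxonomy\txrefs"]
    n_catalysed = 0
    for e in range(spec.n_enzymes):
        uniprot = f"P{e + 1:05d}"
        entry = f"FIX{e + 1}_SYNTH"
        name = f"fixture enzyme {e + 1}"
        taxon = 1 + (e % n_org) if n_org > 1 else 1
        j = e % spec.n_reactions
        # alternate xref spellings to exercise namespace normalisation
        if e % 2 == 0:
            rx = f"mnx:{rxn_ids[j]}"
        else:
            rx = f"kegg:R{j + 1:05d}"
        protein_rows.append(
            f"{uniprot}\t{entry}\t{name}\t\t2.7.1.{e + 1}\t{taxon}\t{rx}"
        )
        n_catalysed += 1
    _write(out_dir / PROTEINS, protein_rows)

    return FixtureGroundTruth(
        n_organisms=n_org,
        n_taxonomy_edges=n_org - 1,
        n_enzymes=spec.n_enzymes,
        n_expresses=spec.n_enzymes,
        n_catalysed_by=n_catalysed,
        n_reactions=spec.n_reactions,
        n_chemicals=n,
        n_chemical_relations=max(0, n_shared - 1),
        unbalanced=unbalanced,
        shared_pairs=shared_pairs,
        canonical_of=canonical_of,
        proton_id=canonical_of[proton],
        water_id=canonical_of[water],
    )


def _write(path: Path, lines: list[str]) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
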