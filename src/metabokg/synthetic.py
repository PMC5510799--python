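"""Synthetic in-memory scenario graphs with known ground truth.

These builders complement :mod:`metabokg.source_io` (which writes source
*files*): they assemble ready-made :class:`~metabokg.model.KnowledgeGraph`
instances directly, for worked examples, tests and benchmarks.  All content
is synthetic — constructed to the documented shapes and sizes, not
extracted from any live database.
"""

from __future__ import annotations

import random

from .chem import annotate_cofactors
from .model import (
    ChemicalEntity,
    EnzymeEntity,
    KnowledgeGraph,
    OrganismEntity,
    Participant,
    ReactionEntity,
    Relationship,
)


def _add_reaction(graph: KnowledgeGraph, rxn: ReactionEntity) -> None:
    graph.upsert_node("Reaction", rxn)
    for p in rxn.participants:
        graph.add_relationship(
            Relationship.make(rxn.id, p.chemical_id, "has_reactant",
                              stoichiometry=p.stoichiometry)
        )


def glucokinase_example(annotate: bool = True) -> KnowledgeGraph:
    """The glucokinase neighbourhood: a hexose-phosphorylating reaction in
    *Escherichia coli* K-12.

    Organism 83333 (E. coli K-12, child of taxon 562) expresses Glucokinase
    (P0A6V8), which catalyses the KEGG reaction R00299: D-glucopyranose +
    ATP(4-) -> D-glucopyranose 6-phosphate(2-) + ADP(3-).  Two auxiliary
    kinase reactions also turn ATP over, so the ATP/ADP couple is detected
    as a frequent pair and relabelled ``has_cofactor``, leaving glucose and
    glucose 6-phosphate as the reactants.
    """
    g = KnowledgeGraph()
    g.upsert_node("Organism", OrganismEntity(
        "562", "Escherichia coli", names=["Bacillus coli Migula 1895"]))
    g.upsert_node("Organism", OrganismEntity(
        "83333", "Escherichia coli K-12", parent_taxonomy="562"))
    g.add_relationship(Relationship.make("83333", "562", "is_a"))

    g.upsert_node("Enzyme", EnzymeEntity(
        "P0A6V8", entry="GLK_ECOLI", ec_code=["2.7.1.2"], name="Glucokinase"))
    g.add_relationship(
        Relationship.make("83333", "P0A6V8", "expresses", source="uniprot"))

    chems = [
        ChemicalEntity("CHEBI:4167", "D-glucopyranose", formula="C6H12O6",
                       charge=0, xrefs={"chebi": "CHEBI:4167"},
                       source="chebi"),
        ChemicalEntity("CHEBI:61548", "D-glucopyranose 6-phosphate(2-)",
                       formula="C6H11O9P", charge=-2,
                       xrefs={"chebi": "CHEBI:61548"}, source="chebi"),
        ChemicalEntity("CHEBI:30616", "ATP(4-)", formula="C10H12N5O13P3",
                       charge=-4, xrefs={"chebi": "CHEBI:30616"},
                       source="chebi"),
        ChemicalEntity("CHEBI:456216", "ADP(3-)", formula="C10H12N5O10P2",
                       charge=-3, xrefs={"chebi": "CHEBI:456216"},
                       source="chebi"),
        # substrates of the auxiliary kinase reactions
        ChemicalEntity("CHEBI:17754", "glycerol", formula="C3H8O3", charge=0,
                       source="chebi", xrefs={"chebi": "CHEBI:17754"}),
        ChemicalEntity("CHEBI:57597", "sn-glycerol 3-phosphate(2-)",
                       formula="C3H7O6P", charge=-2, source="chebi",
                       xrefs={"chebi": "CHEBI:57597"}),
        ChemicalEntity("CHEBI:15946", "D-ribose", formula="C5H10O5",
                       charge=0, source="chebi",
                       xrefs={"chebi": "CHEBI:15946"}),
        ChemicalEntity("CHEBI:52742", "D-ribose 5-phosphate(2-)",
                       formula="C5H9O8P", charge=-2, source="chebi",
                       xrefs={"chebi": "CHEBI:52742"}),
    ]
    for chem in chems:
        g.upsert_node("Chemical", chem)
    g.add_relationship(Relationship.make(
        "CHEBI:61548", "CHEBI:4167", "has_functional_parent"))

    r00299 = ReactionEntity(
        "MNXR0299", ec=["2.7.1.2"], source="mnxref",
        xrefs={"mnx": "MNXR0299", "kegg.reaction": "R00299"},
        participants=[
            Participant("CHEBI:4167", -1),
            Participant("CHEBI:30616", -1),
            Participant("CHEBI:61548", +1),
            Participant("CHEBI:456216", +1),
        ],
    )
    _add_reaction(g, r00299)
    g.add_relationship(Relationship.make(
        "MNXR0299", "P0A6V8", "catalysed_by", source="kegg.reaction"))
    for i, (a, b) in enumerate(
        [("CHEBI:17754", "CHEBI:57597"), ("CHEBI:15946", "CHEBI:52742")]
    ):
        _add_reaction(g, ReactionEntity(
            f"MNXR9{i:03d}", source="mnxref",
            xrefs={"mnx": f"MNXR9{i:03d}"},
            participants=[
                Participant(a, -1), Participant("CHEBI:30616", -1),
                Participant(b, +1), Participant("CHEBI:456216", +1),
            ],
        ))
    if annotate:
        annotate_cofactors(g, min_pair_count=2)
    return g


def flavonoid_ontology(
    n_compounds: int = 1081, n_classes: int = 26, seed: int = 0
) -> KnowledgeGraph:
    """A synthetic flavonoid class hierarchy.

    A root Chemical named ``flavonoid`` (a class node, no formula) carries
    ``n_classes`` intermediate subclasses, also without formulas (like
    "flavans" in a real ontology), and ``n_compounds`` leaf compounds with
    specific formulas, ChEBI ids and InChI strings attached below them.
    The default sizes mirror a flavonoid chemical-space survey in which the
    descendant query returns 1081 specific structures.
    """
    rng = random.Random(seed)
    g = KnowledgeGraph()
    root = ChemicalEntity("CHEBI:47916", "flavonoid",
                          xrefs={"chebi": "CHEBI:47916"}, source="chebi")
    g.upsert_node("Chemical", root)
    class_ids = []
    for c in range(n_classes):
        cid = f"CHEBI:{60000 + c}"
        g.upsert_node("Chemical", ChemicalEntity(
            cid, f"flavonoid class {c}", xrefs={"chebi": cid},
            source="chebi"))
        # classes form a shallow tree under the root
        parent = root.id if c < 6 else class_ids[rng.randrange(c)]
        g.add_relationship(Relationship.make(cid, parent, "is_a"))
        class_ids.append(cid)
    rel_types = ("is_a", "has_functional_parent", "is_conjugate_base_of")
    for i in range(n_compounds):
        cid = f"CHEBI:{100000 + i}"
        c, h, o = 15 + i % 10, 10 + i % 8, 4 + i % 7
        g.upsert_node("Chemical", ChemicalEntity(
            cid, f"flavonoid-{i}", formula=f"C{c}H{h}O{o}",
            inchi=f"InChI=1S/C{c}H{h}O{o}/synthetic-{i}",
            xrefs={"chebi": cid}, source="chebi"))
        parent = class_ids[rng.randrange(n_classes)]
        g.add_relationship(
            Relationship.make(cid, parent, rel_types[i % len(rel_types)]))
    return g


def strain_metabolome(
    n_in_window: int = 111,
    mass_min: float = 400.0,
    mass_max: float = 500.0,
    n_strains: int = 3,
    n_decoys: int = 30,
    seed: int = 0,
) -> KnowledgeGraph:
    """A synthetic strain-level metabolome around a parent taxon (562).

    ``n_strains`` strain organisms sit one ``is_a`` hop below taxon 562;
    each expresses enzymes whose reactions consume/produce the metabolite
    pool.  Exactly ``n_in_window`` metabolites get monoisotopic masses
    strictly inside (mass_min, mass_max); decoys fall outside the window,
    sit exactly on its edge, join reactions only as cofactors, or hang off
    an unrelated taxon.  The default window and count mirror a strain-wide
    metabolite survey returning 111 species between 400 and 500 Da.
    """
    rng = random.Random(seed)
    g = KnowledgeGraph()
    g.upsert_node("Organism", OrganismEntity("562", "Escherichia coli"))
    g.upsert_node("Organism", OrganismEntity("2", "unrelated taxon"))
    strains = []
    for s in range(n_strains):
        tid = str(83333 + s)
        g.upsert_node("Organism", OrganismEntity(
            tid, f"E. coli strain {s}", parent_taxonomy="562"))
        g.add_relationship(Relationship.make(tid, "562", "is_a"))
        strains.append(tid)

    span = mass_max - mass_min
    chems: list[tuple[str, float]] = []
    for i in range(n_in_window):
        mass = mass_min + (i + 1) * span / (n_in_window + 1)
        cid = f"CHEBI:{200000 + i}"
        g.upsert_node("Chemical", ChemicalEntity(
            cid, f"metabolite-{i}", formula=f"C20H{20 + i % 20}O{6 + i % 5}",
            charge=-(i % 3), monoisotopic_mass=round(mass, 4),
            xrefs={"chebi": cid}, source="chebi"))
        chems.append((cid, mass))
    decoys = []
    for i in range(n_decoys):
        cid = f"CHEBI:{250000 + i}"
        mass = [mass_min - 50.0, mass_max + 50.0, mass_min, mass_max][i % 4]
        g.upsert_node("Chemical", ChemicalEntity(
            cid, f"decoy-{i}", formula="C10H10O5", charge=0,
            monoisotopic_mass=mass, xrefs={"chebi": cid}, source="chebi"))
        decoys.append(cid)
    cof_id = "CHEBI:260000"
    g.upsert_node("Chemical", ChemicalEntity(
        cof_id, "cofactor-linked", monoisotopic_mass=450.0,
        formula="C21H26N7O14P2", charge=-3, xrefs={"chebi": cof_id},
        source="chebi"))

    for j in range(0, n_in_window, 2):
        rid = f"MNXR{7000 + j}"
        parts = [Participant(chems[j][0], -1)]
        if j + 1 < n_in_window:
            parts.append(Participant(chems[j + 1][0], +1))
        else:
            parts.append(Participant(decoys[0], +1))
        parts.append(Participant(decoys[(j // 2) % n_decoys],
                                 +1 if j % 4 else -1))
        rxn = ReactionEntity(rid, source="mnxref",
                             xrefs={"mnx": rid}, participants=parts)
        _add_reaction(g, rxn)
        g.add_relationship(Relationship.make(
            rid, cof_id, "has_cofactor", stoichiometry=-1))
        enz = f"P{40000 + j}"
        g.upsert_node("Enzyme", EnzymeEntity(enz, name=f"enzyme-{j}"))
        g.add_relationship(Relationship.make(
            rid, enz, "catalysed_by", source="kegg.reaction"))
        g.add_relationship(Relationship.make(
            strains[rng.randrange(n_strains)], enz, "expresses",
            source="uniprot"))
    # an in-window chemical reachable only from the unrelated taxon would
    # break the ground truth, so the unrelated branch gets a decoy instead
    rid, enz = "MNXR9999", "P49999"
    g.upsert_node("Enzyme", EnzymeEntity(enz, name="unrelated enzyme"))
    _add_reaction(g, ReactionEntity(
        rid, source="mnxref", xrefs={"mnx": rid},
        participants=[Participant(decoys[1], -1), Participant(decoys[2], +1)],
    ))
    g.add_relationship(Relationship.make(rid, enz, "catalysed_by",
                                         source="kegg.reaction"))
    g.add_relationship(Relationship.make("2", enz, "expresses",
                                         source="uniprot"))
    return g


def random_reaction_network(
    n_chemicals: int = 40,
    n_reactions: int = 40,
    seed: int = 0,
    host_fraction: float = 0.3,
) -> KnowledgeGraph:
    """A random bipartite reaction network for pathway-search stress tests.

    Each reaction draws 2-4 distinct chemicals with random sides and
    coefficients in {1, 2} (at least one consumed, one produced).  A host
    organism (taxonomy "9000") expresses one enzyme per reaction for
    roughly ``host_fraction`` of the reactions, defining the native
    chemical set.
    """
    rng = random.Random(seed)
    g = KnowledgeGraph()
    g.upsert_node("Organism", OrganismEntity("9000", "host organism"))
    chem_ids = [f"C{i:03d}" for i in range(n_chemicals)]
    for cid in chem_ids:
        g.upsert_node("Chemical", ChemicalEntity(
            cid, f"chemical {cid}", source="synthetic"))
    for j in range(n_reactions):
        k = rng.randint(2, min(4, n_chemicals))
        members = rng.sample(chem_ids, k)
        parts = [Participant(members[0], -rng.randint(1, 2)),
                 Participant(members[1], +rng.randint(1, 2))]
        for cid in members[2:]:
            parts.append(Participant(
                cid, rng.choice([-1, 1]) * rng.randint(1, 2)))
        rid = f"R{j:03d}"
        _add_reaction(g, ReactionEntity(rid, source="synthetic",
                                        participants=parts))
        if rng.random() < host_fraction:
            enz = f"E{j:03d}"
            g.upsert_node("Enzyme", EnzymeEntity(enz))
            g.add_relationship(Relationship.make(
                rid, enz, "catalysed_by", source="synthetic"))
            g.add_relationship(Relationship.make(
                "9000", enz, "expresses", source="synthetic"))
    return g
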