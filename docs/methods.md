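# Methods

## The graph model

The store is a labelled property graph with four node labels — Organism,
Enzyme, Reaction, Chemical — and a closed set of directed relationship
signatures: taxonomic `is_a` (Organism→Organism), `expresses`
(Organism→Enzyme), `catalysed_by` (Reaction→Enzyme), `has_reactant` and
`has_cofactor` (Reaction→Chemical, carrying an integer `stoichiometry`
property), and nine chemical-ontology types (Chemical→Chemical: `is_a`,
`has_functional_parent`, `has_parent_hydride`, `has_part`,
`is_conjugate_acid_of`, `is_conjugate_base_of`, `is_enantiomer_of`,
`is_substituent_group_from`, `is_tautomer_of`). Any relationship outside
these signatures, or touching a missing node, is rejected at insert time.

Node keys are the unique identifying columns of each entity: `id` for
chemicals and reactions, the UniProt accession for enzymes, the NCBI
taxonomy id for organisms. Fully identical edges (same endpoints, type and
properties) deduplicate; edges differing in any property — notably the
provenance `source` — are kept as distinct parallel edges, so merging
sources never silently discards provenance. The store is in-memory and
insertion-ordered; exports sort by key, making the bulk CSV byte-stable.

Stoichiometry follows the constraint-based-modelling convention: negative
integers are consumed (reactant side), positive produced (product side).

`summary_stats` reports, per ordered label pair, the number of first-label
nodes with at least one such relationship, the edge count, and the node
count as a percentage of the label. Edges are stored in one direction only
but reported in both orientations (e.g. Organism–Enzyme and
Enzyme–Organism); for same-label pairs only the From side is counted, so in
a taxonomy chain of *n* organisms the coverage is (n−1)/n — the root has no
parent.

## Source dialects

Real releases of public flat files vary by version, so the parsers freeze
small documented dialects (tab-pipe-tab taxonomy dumps, '#'-commented
TSVs, a four-table ontology dump, a seven-column protein table; see the
`source_io` module docstring). They accept LF/CRLF, skip blanks and
comments, and fail loudly with file/line positions on malformed input.
Reaction equations use `coef id (+ coef id)* = coef id (+ coef id)*` with
coefficient default 1; a chemical appearing on both sides is netted (equal
coefficients cancel away entirely, with a warning). Reaction↔enzyme links
arrive as `namespace:accession` tokens on the protein table and are
resolved against the reaction cross-reference index after all reactions
load; unresolved links are reported and dropped at build end.

## Identifier normalisation and merging

Namespace tokens are normalised case-insensitively to identifiers.org keys
through an extensible table; ambiguous tokens (e.g. `kegg`, `seed`,
`bigg`) are resolved by the node-label context. Unknown tokens raise an
explicit error rather than passing through, so silent identifier drift
cannot occur. ChEBI accessions are canonicalised to the `CHEBI:<n>` form.

Entities of one label merge iff they share at least one
(namespace, accession) pair; sharing is closed transitively with
union-find. Name equality is deliberately *not* a merge key — names are too
ambiguous. Within a merged component a source-precedence list (default
`chebi > mnxref` for chemicals, `mnxref > kegg` for reactions,
configurable) selects the canonical node key and wins scalar property
conflicts; every losing value is logged in the MergeReport, and losing
names are demoted to synonyms. Contradictory accessions in a second shared
namespace do not block the merge; they are logged as conflicts. The
operation is idempotent: after one pass no two nodes share any pair.

## Reaction balancing

A reaction is balanced when every element and the net charge are conserved
over its signed stoichiometries. Balancing solves an integer program over:

* one integer coefficient per existing participant, bounded in
  [1, max_coefficient] (default 20) and pinned to its original side —
  participants may not vanish or switch sides, which would silently change
  reaction semantics;
* one integer coefficient ≥ 0 per addable species per side. The default
  addable set is H⁺ and H₂O, the species most often missing from curated
  reaction definitions; the set is configurable.

The objective is lexicographic: (1) minimise total absolute deviation from
the original coefficients — "respecify as little as possible"; (2) minimise
the total amount of added species; (3) prefer species earlier in the
addable list (H⁺ before H₂O); (4) minimise the total coefficient sum. This
is realised as one weighted objective (tiers 10⁶ / 10³ / 10 / 10⁻²) whose
ratios are asserted at solve time to exceed the maximum attainable value of
all lower tiers under the coefficient bound, making the ordering exact. The
MILP is solved with HiGHS via `scipy.optimize.milp`; reaction sizes make
this inexpensive.

Outcomes are tri-state plus a repair record: `already_balanced`,
`rebalanced` (with a participant delta), `unbalanceable` (infeasible within
the bound), or `unknown` when any participant lacks a parseable specific
formula or a charge — one generic participant poisons the whole reaction,
which keeps its flag unset rather than guessing.

During a build the balancing pass runs *before* cofactor annotation, so
solver-added protons and water are immediately classified as cofactors by
the mass rule and never pollute pathway traversal.

## Formulas, masses and cofactors

`parse_formula` accepts plain `(ElementSymbol Count?)+` formulas with exact
integer counts. Parenthesised groups, `*`, R/X groups and trailing `n`
repeats denote generic classes or polymers and raise a dedicated error;
callers treat such chemicals as class nodes (storable, but massless and
unusable for balancing). Monoisotopic mass is the sum of count × the most
abundant isotope's exact mass, from a bundled table (AME2020 values,
67 elements, 10⁻⁷ Da precision); tests assert to 10⁻⁴ Da.

Cofactors are identified by two load-time rules:

* **Low mass**: monoisotopic mass strictly below 44 Da (water, ammonia,
  protons — and CO₂, whose monoisotopic mass 43.9898 Da falls just under
  the threshold; the strict reading is retained deliberately).
* **Frequent pairs**: unordered chemical pairs occurring with opposite
  signs in at least `min_pair_count` reactions (default
  max(2, ⌈5% of reactions⌉) — large enough to catch ATP/ADP-style currency
  couples on small networks while scaling with network size). Both members
  of a detected pair are relabelled, but only inside reactions where both
  appear with opposite signs, so a lone ATP reactant remains visible to
  pathway search.

Relabelling changes only the edge type; stoichiometries and the total
Reaction–Chemical edge count are preserved.

## Queries

*Context*: a reaction (looked up by cross-reference) occurs in an organism
iff some enzyme both catalyses it and is expressed by that organism; the
returned subgraph adds the reaction's chemicals, the organism's parent
taxon and ontology edges among the returned chemicals.

*Descendants*: transitive closure over all nine ontology types, traversed
against the stored child→parent direction, with a visited set (cycles in
relation data terminate cleanly). The formula filter drops class nodes.
Several roots with the same name are all used and reported.

*Metabolome*: follows Chemical ←has_reactant– Reaction –catalysed_by→
Enzyme ←expresses– Organism –is_a→ taxon with strict mass bounds
(`>`/`<`); cofactor edges are excluded. The taxon hop is one `is_a` level
by default, with a `transitive` flag for deeper strain hierarchies.

*Pathways*: the search runs on the bipartite chemical/reaction graph of
`has_reactant` edges treated as undirected; direction is supplied entirely
by the sign rule — the product of every two consecutive edge
stoichiometries along the path must be negative. This single constraint
enforces both reactant→product traversal through each reaction and
produced-then-consumed alternation at each intermediate chemical. Source
chemicals are those attached (either sign by default; a `produced_only`
flag restricts to products) to reactions catalysed by enzymes the host
expresses. Paths are simple — cycles would make "shortest" ill-defined
under sign alternation — and bounded by `max_len` reactions (default 8).
Iterative deepening returns all minimum-length pathways, ordered
lexicographically by node sequence for determinism; a host-native target
yields one length-0 pathway. Reactions along returned pathways can then be
joined back to every catalysing enzyme and expressing organism.

## Export

Bulk CSV follows the neo4j-admin import header convention (`:ID`,
`:LABEL`, `:START_ID`, `:END_ID`, `:TYPE`, typed columns, ';'-delimited
arrays), UTF-8 with LF endings and RFC-4180 quoting, one file per node
label and per relationship type plus a JSON manifest with row counts.
Write∘read is the identity up to canonical ordering (reaction participant
order is not preserved — participants are recovered from edges — and
read-back is verified as a multiset). Unknown columns are kept as loose
string properties with a warning. Query results export as CSV or a JSON
array of objects.

## Synthetic data

Two generators provide ground truth without any downloads.

`source_io.generate_fixture` writes the full set of source files for a
parameterised scenario: a taxonomy tree of given size and depth, a
chemical pool built from a proton, water and substrate/product pairs
(CₖH₂ₖOₖ → CₖH₂ₖ₊₁Oₖ₊₁⁻), and hydration reactions `A + H₂O → P⁻ + H⁺` that
are exactly balanced by construction. A configurable fraction of reactions
is written with the proton stripped (ground truth records the original
stoichiometries, so balancing recovery is checkable exactly), and a
configurable fraction of chemicals is emitted by both the MNXref-style and
ChEBI-style files under linked cross-references (so the post-merge node
count is known exactly). Defaults — 50 taxa, 30 enzymes, 20 reactions,
40 chemicals, 25% corrupted, 25% shared — give a miniature but structurally
complete graph. Generation is deterministic per seed, byte-identical
across runs.

`synthetic` builds in-memory scenario graphs: the glucokinase
neighbourhood (context query with 2 reactants + 2 cofactors), a flavonoid
class hierarchy whose formula-bearing descendant count is 1081 by
construction, a strain metabolome with exactly 111 species strictly inside
the 400–500 Da window plus boundary/cofactor/unrelated-taxon decoys, and
random bipartite reaction networks for pathway stress tests. The flavonoid
and metabolome builders are synthetic stand-ins sized to the documented
survey results; they exercise the real query code on graphs with those
known answers.

What the generators do *not* emulate: real identifier collision patterns
(xref links are constructed, never wrong), chemistry beyond C/H/O
hydration stoichiometry, polymer/R-group formulas in reactions, multiple
name classes beyond one synonym layer, and the scale of live releases
(millions of nodes). Passing tests demonstrate correctness of the
algorithms on known ground truth, not robustness to every formatting
quirk of real dumps — though the parsers do accept the documented real
dialect shapes.

## Problem sizes and verification

The test suite and acceptance script run everything at desk scale: the
default fixture (50/30/20/40), 50 random pathway networks of up to
40 chemicals and 40 reactions checked against exhaustive enumeration with
`max_len` 6, 12 random ≤5-participant balancing problems checked against
exhaustive enumeration with coefficients ≤ 3, 20 round-trip fixtures, and
the two survey scenarios (1081 and 111). Oracles are independent
implementations: networkx simple-path enumeration for pathways, brute-force
coefficient search for balancing, boolean matrix powers for ontology
closure, and per-node scans for statistics.

## Known limitations

* Chemical identity is established only through shared cross-references;
  structure-based identity (InChI-key canonicalisation) is a natural
  extension but not implemented.
* Balancing ignores pH-dependent charge states and cannot handle polymeric
  species; charge is taken as stored.
* The frequent-pair cofactor rule is a heuristic; on very small networks
  the 5% threshold floor of 2 can relabel genuine substrate/product pairs
  that recur.
* `find_pathways` enumerates all shortest sign-valid simple paths; on
  dense networks with long `max_len` this is exponential in the worst
  case. The sign-alternation rule admits either orientation of a path
  (the printed traversal pattern is symmetric); no thermodynamic or
  atom-mapping filter is applied.
* The store is not transactional and has no persistence beyond the bulk
  CSV export; a live graph-database server is intentionally out of scope.
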