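"""Independent brute-force oracles used to cross-check the package.

Everything here recomputes results from first principles (exhaustive
enumeration, closure by matrix powers, plain censuses) without touching the
implementation paths under test.
"""

from __future__ import annotations

import itertools
from collections import Counter

import networkx as nx
import numpy as np


def brute_force_pathways(graph, host_taxon_id, target_chemical_id,
                         max_len=8):
    """All minimum-length sign-valid simple pathways, by exhaustive
    enumeration over the bipartite has_reactant graph via networkx."""
    rels = graph.relationships
    enzymes = {r.to_id for r in rels
               if r.type == "expresses" and r.from_id == host_taxon_id}
    host_rxns = {r.from_id for r in rels
                 if r.type == "catalysed_by" and r.to_id in enzymes}
    sources = {r.to_id for r in rels
               if r.type == "has_reactant" and r.from_id in host_rxns}
    if target_chemical_id in sources:
        return [[target_chemical_id]]
    bg = nx.Graph()
    stoich = {}
    for r in rels:
        if r.type == "has_reactant":
            bg.add_edge(r.from_id, r.to_id)
            stoich[(r.from_id, r.to_id)] = dict(r.properties)["stoichiometry"]
    valid = []
    for src in sources:
        if src not in bg or target_chemical_id not in bg:
            continue
        for path in nx.all_simple_paths(bg, src, target_chemical_id,
                                        cutoff=2 * max_len):
            if len(path) % 2 == 0:
                continue  # must end on a chemical
            signs = []
            ok = True
            for a, b in zip(path, path[1:]):
                key = (a, b) if (a, b) in stoich else (b, a)
                if key not in stoich:
                    ok = False
                    break
                signs.append(stoich[key])
            if not ok:
                continue
            if all(x * y < 0 for x, y in zip(signs, signs[1:])):
                valid.append(path)
    if not valid:
        return []
    shortest = min(len(p) for p in valid)
    return sorted(p for p in valid if len(p) == shortest)


def enumerate_balance_optimum(participants, vectors, addables, max_coef):
    """Exhaustively minimise the lexicographic balancing objective.

    ``vectors`` maps participant index -> (element counts dict, charge);
    ``addables`` is a list of (counts, charge) usable on either side.
    Returns the optimal (total deviation, total added, preference penalty,
    coefficient sum) tuple or None if infeasible.
    """
    m = len(participants)
    sides = [1 if p.stoichiometry > 0 else -1 for p in participants]
    orig = [abs(p.stoichiometry) for p in participants]
    best = None
    add_ranges = [range(0, max_coef + 1)] * (2 * len(addables))
    for coefs in itertools.product(range(1, max_coef + 1), repeat=m):
        for adds in itertools.product(*add_ranges):
            totals = Counter()
            charge = 0
            for i in range(m):
                counts, ch = vectors[i]
                for e, n in counts.items():
                    totals[e] += sides[i] * coefs[i] * n
                charge += sides[i] * coefs[i] * ch
            for a, (counts, ch) in enumerate(addables):
                for side_idx, side in enumerate((-1, +1)):
                    z = adds[2 * a + side_idx]
                    for e, n in counts.items():
                        totals[e] += side * z * n
                    charge += side * z * ch
            if charge != 0 or any(v != 0 for v in totals.values()):
                continue
            dev = sum(abs(c - o) for c, o in zip(coefs, orig))
            added = sum(adds)
            pref = sum(
                a * (adds[2 * a] + adds[2 * a + 1])
                for a in range(len(addables))
            )
            total = sum(coefs) + added
            cand = (dev, added, pref, total)
            if best is None or cand < best:
                best = cand
    return best


def pair_census(reactions):
    """O(reactions x pairs) opposite-sign co-occurrence counts."""
    chem_ids = sorted(
        {p.chemical_id for r in reactions for p in r.participants}
    )
    counts = Counter()
    for a, b in itertools.combinations(chem_ids, 2):
        for rxn in reactions:
            sa = [p.stoichiometry for p in rxn.participants
                  if p.chemical_id == a]
            sb = [p.stoichiometry for p in rxn.participants
                  if p.chemical_id == b]
            if sa and sb and sa[0] * sb[0] < 0:
                counts[(a, b)] += 1
    return counts


def closure_descendants(graph, root_ids):
    """Transitive closure by boolean matrix powers over the chemical
    ontology edges (stored child -> parent)."""
    from metabokg.model import CHEMICAL, CHEMICAL_RELATION_TYPES

    ids = sorted(graph.nodes[CHEMICAL])
    idx = {cid: i for i, cid in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)  # parent -> child
    for rel in graph.relationships:
        if rel.type in CHEMICAL_RELATION_TYPES and rel.from_id in idx \
                and rel.to_id in idx:
            adj[idx[rel.to_id], idx[rel.from_id]] = True
    reach = adj.copy()
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    out = set()
    for root in root_ids:
        out |= {ids[j] for j in np.nonzero(reach[idx[root]])[0]}
    return out - set(root_ids)


def coverage_scan(graph):
    """Per-node brute-force recount of summary-stat coverage percentages."""
    out = {}
    pairs = set()
    label_of = {key: lb for lb in graph.nodes for key in graph.nodes[lb]}
    for rel in graph.relationships:
        fl, tl = label_of[rel.from_id], label_of[rel.to_id]
        pairs.add((fl, tl))
        if fl != tl:
            pairs.add((tl, fl))
    for (a, b) in pairs:
        have = 0
        for key in graph.nodes[a]:
            hit = any(
                label_of[r.to_id] == b for r in graph.out_edges(key)
            ) or (
                a != b
                and any(label_of[r.from_id] == b for r in graph.in_edges(key))
            )
            if hit:
                have += 1
        out[f"{a}-{b}"] = 100.0 * have / len(graph.nodes[a])
    return out
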