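"""Molecular-formula arithmetic and cofactor classification.

Cofactors are reaction participants excluded from pathway traversal.  Two
load-time rules identify them: a low-molecular-mass rule (monoisotopic mass
strictly below 44 Da — water, protons, ammonia, and, at 43.9898 Da, CO2)
and a frequent-pair rule for currency couples such as ATP/ADP that occur
with opposite signs in many reactions of the network.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .errors import (
    FormulaError,
    GenericFormulaError,
    UnknownElementError,
)
from .model import (
    REACTION,
    ChemicalEntity,
    KnowledgeGraph,
    ReactionEntity,
    Relationship,
)

#: Monoisotopic mass threshold (Da) below which a compound is a cofactor.
LOW_MASS_THRESHOLD = 44.0


def _load_isotope_masses() -> dict[str, float]:
    table = {}
    text = (
        resources.files("metabokg").joinpath("data/isotope_masses.tsv")
        .read_text(encoding="utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


#: Exact mass of the most abundant isotope per element symbol, in Da.
ISOTOPE_MASSES: dict[str, float] = _load_isotope_masses()

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
#: Symbols that denote generic groups/repeats, not elements.
_GENERIC_SYMBOLS = {"R", "X"}
_GENERIC_CHARS = set("()[]{}*.")


@dataclass
class ElementVector:
    """Element counts plus a net charge; the unit of mass/charge bookkeeping."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __add__(self, other: "ElementVector") -> "ElementVector":
        c = Counter(self.counts)
        c.update(other.counts)
        return ElementVector(dict(c), self.charge + other.charge)

    def scaled(self, k: int) -> "ElementVector":
        return ElementVector(
            {e: n * k for e, n in self.counts.items()}, self.charge * k
        )

    def elements(self) -> set[str]:
        return set(self.counts)


def parse_formula(formula: str) -> ElementVector:
    """Parse a plain molecular formula like ``C6H12O6`` into element counts.

    Only ``(ElementSymbol Count?)+`` is accepted.  Parenthesised groups,
    ``*``, R-groups and polymeric ``n`` repeats mark a generic class formula
    and raise :class:`GenericFormulaError`; an unrecognised element symbol
    raises :class:`UnknownElementError`.  Repeated symbols accumulate.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError(f"empty formula {formula!r}")
    formula = formula.strip()
    if _GENERIC_CHARS & set(formula) or formula.endswith("n"):
        raise GenericFormulaError(f"generic/polymeric formula {formula!r}")
    if not formula.isalnum():
        raise FormulaError(f"illegal characters in formula {formula!r}")
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if not m or m.start() != pos or not m.group(0):
            raise FormulaError(
                f"cannot parse formula {formula!r} at offset {pos}"
            )
        symbol, digits = m.groups()
        if symbol in _GENERIC_SYMBOLS and symbol not in ISOTOPE_MASSES:
            raise GenericFormulaError(
                f"generic group {symbol!r} in formula {formula!r}"
            )
        if symbol not in ISOTOPE_MASSES:
            raise UnknownElementError(
                f"unknown element {symbol!r} in formula {formula!r}"
            )
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(
                f"zero count for {symbol!r} in formula {formula!r}"
            )
        counts[symbol] += n
        pos = m.end()
    return ElementVector(dict(counts), 0)


def monoisotopic_mass(ev: ElementVector) -> float:
    """Sum of count x most-abundant-isotope mass over the vector's elements."""
    try:
        return sum(n * ISOTOPE_MASSES[e] for e, n in ev.counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise UnknownElementError(f"no isotope mass for element {exc}") from exc


def chemical_mass(chemical: ChemicalEntity) -> Optional[float]:
    """Monoisotopic mass of a chemical: the stored value if present, else
    computed from the formula; None if neither is usable."""
    if chemical.monoisotopic_mass is not None:
        return chemical.monoisotopic_mass
    if chemical.formula:
        try:
            return monoisotopic_mass(parse_formula(chemical.formula))
        except FormulaError:
            return None
    return None


def is_low_mass_cofactor(chemical: ChemicalEntity) -> bool:
    """True iff the chemical's monoisotopic mass is strictly below 44 Da.

    Chemicals without a mass and without a parseable formula (generic class
    nodes) are never low-mass cofactors.
    """
    mass = chemical_mass(chemical)
    return mass is not None and mass < LOW_MASS_THRESHOLD


def default_min_pair_count(n_reactions: int) -> int:
    """Load-time default for the frequent-pair threshold: max(2, 5% of
    the reaction count)."""
    return max(2, math.ceil(0.05 * n_reactions))


def detect_frequent_pairs(
    reactions: Iterable[ReactionEntity], min_pair_count: int
) -> set[tuple[str, str]]:
    """Unordered chemical pairs occurring with opposite stoichiometry signs
    in at least ``min_pair_count`` reactions (e.g. ATP consumed while ADP is
    produced).  Pairs co-occurring on the same side only do not count."""
    if min_pair_count < 2:
        raise ValueError("min_pair_count must be >= 2")
    census: Counter[tuple[str, str]] = Counter()
    for rxn in reactions:
        consumed = {p.chemical_id for p in rxn.participants
                    if p.stoichiometry < 0}
        produced = {p.chemical_id for p in rxn.participants
                    if p.stoichiometry > 0}
        seen = set()
        for a in consumed:
            for b in produced:
                if a != b:
                    seen.add(tuple(sorted((a, b))))
        census.update(seen)
    return {pair for pair, n in census.items() if n >= min_pair_count}


def annotate_cofactors(
    graph: KnowledgeGraph, min_pair_count: Optional[int] = None
) -> int:
    """Relabel ``has_reactant`` edges to ``has_cofactor`` per the two rules.

    A participant becomes a cofactor if it is a low-mass compound, or if it
    belongs to a detected frequent pair whose partner participates in the
    same reaction with opposite sign.  Stoichiometries are preserved and the
    total Reaction-Chemical edge count is unchanged.  Returns the number of
    relabelled edges.
    """
    reactions = list(graph.nodes[REACTION].values())
    if min_pair_count is None:
        min_pair_count = default_min_pair_count(len(reactions))
    pairs = detect_frequent_pairs(reactions, min_pair_count)
    relabelled = 0
    for rxn in reactions:
        for p in rxn.participants:
            chem = graph.get("Chemical", p.chemical_id)
            cof = chem is not None and is_low_mass_cofactor(chem)
            if not cof:
                for q in rxn.participants:
                    if (
                        q.chemical_id != p.chemical_id
                        and q.stoichiometry * p.stoichiometry < 0
                        and tuple(sorted((p.chemical_id, q.chemical_id)))
                        in pairs
                    ):
                        cof = True
                        break
            if not cof or p.role == "cofactor":
                continue
            p.role = "cofactor"
            for edge in graph.out_edges(rxn.id, "has_reactant"):
                if edge.to_id == p.chemical_id:
                    graph.remove_relationship(edge)
                    graph.add_relationship(
                        Relationship(edge.from_id, edge.to_id,
                                     "has_cofactor", edge.properties)
                    )
                    relabelled += 1
    return relabelled
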