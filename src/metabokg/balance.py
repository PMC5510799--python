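"""Reaction mass- and charge-balancing by integer linear programming.

A reaction is balanced when every element and the net charge are conserved
across its signed stoichiometries.  For unbalanced reactions the solver
searches for corrected non-negative integer coefficients — each participant
keeps its original side and stays non-zero — optionally adding commonly
missing species (protons and water by default) on either side.

The objective is lexicographic minimal perturbation:

1. minimise the total absolute change to existing coefficients,
2. then the total amount of added species,
3. then prefer species earlier in the addable list (H+ before H2O),
4. then the smallest total coefficient sum.

Realised as a single weighted objective whose weight ratios exceed the
maximum attainable value of every lower-priority term, so the ordering is
exact within the default coefficient bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .chem import ElementVector, parse_formula
from .errors import FormulaError
from .model import ChemicalEntity, Participant, ReactionEntity


class BalanceStatus(Enum):
    ALREADY_BALANCED = "already_balanced"
    REBALANCED = "rebalanced"
    UNBALANCEABLE = "unbalanceable"
    UNKNOWN = "unknown"


@dataclass
class BalanceConfig:
    """Solver settings.

    ``addable_species`` lists (chemical_id, formula, charge) triples the
    solver may introduce on either side, in preference order.
    ``max_coefficient`` bounds every coefficient magnitude.
    """

    addable_species: tuple[tuple[str, str, int], ...] = (
        ("H+", "H", 1),
        ("H2O", "H2O", 0),
    )
    max_coefficient: int = 20


@dataclass
class BalanceResult:
    status: BalanceStatus
    participants: list[Participant] = field(default_factory=list)
    delta: list[tuple[str, int, int]] = field(default_factory=list)


def _participant_vectors(
    participants: Sequence[Participant],
    chemicals: Mapping[str, ChemicalEntity],
) -> Optional[list[ElementVector]]:
    """Element/charge vector per participant, or None if any chemical lacks
    a parseable specific formula or a known charge."""
    vectors = []
    for p in participants:
        chem = chemicals.get(p.chemical_id)
        if chem is None or not chem.formula or chem.charge is None:
            return None
        try:
            ev = parse_formula(chem.formula)
        except FormulaError:
            return None
        ev.charge = chem.charge
        vectors.append(ev)
    return vectors


def verify_balance(
    participants: Sequence[Participant],
    chemicals: Mapping[str, ChemicalEntity],
) -> Optional[bool]:
    """Tri-state conservation check.

    True/False when every participant has formula and charge; None when any
    is missing (balance status cannot be decided).  An empty participant
    list is vacuously balanced.
    """
    vectors = _participant_vectors(participants, chemicals)
    if vectors is None:
        return None
    totals: dict[str, int] = {}
    charge = 0
    for p, ev in zip(participants, vectors):
        for e, n in ev.counts.items():
            totals[e] = totals.get(e, 0) + p.stoichiometry * n
        charge += p.stoichiometry * ev.charge
    return charge == 0 and all(v == 0 for v in totals.values())


# objective weight tiers; ratios checked in balance_reaction against the
# coefficient bound so lexicographic ordering is exact
_W_DEV = 1e6
_W_ADD = 1e3
_W_PREF = 10.0
_W_SUM = 0.01


def balance_reaction(
    reaction: ReactionEntity,
    chemicals: Mapping[str, ChemicalEntity],
    config: Optional[BalanceConfig] = None,
) -> BalanceResult:
    """Balance one reaction, returning corrected participants and a delta.

    Participants whose chemical lacks formula or charge poison the whole
    reaction (status UNKNOWN, nothing changed).  Infeasibility within the
    coefficient bound yields UNBALANCEABLE.
    """
    config = config or BalanceConfig()
    participants = list(reaction.participants)
    vectors = _participant_vectors(participants, chemicals)
    if vectors is None:
        return BalanceResult(BalanceStatus.UNKNOWN, participants, [])
    if verify_balance(participants, chemicals):
        return BalanceResult(BalanceStatus.ALREADY_BALANCED, participants, [])

    present_ids = {p.chemical_id for p in participants}
    addables = []  # (chemical_id, vector, side, preference_index)
    for pref, (chem_id, formula, charge) in enumerate(config.addable_species):
        if chem_id in present_ids:
            continue  # already a participant; respecified like any other
        ev = parse_formula(formula)
        ev.charge = charge
        for side in (-1, +1):
            addables.append((chem_id, ev, side, pref))

    m = len(participants)
    k = len(addables)
    n_var = 2 * m + k  # [c_0..c_m-1, d_0..d_m-1, z_0..z_k-1]
    max_c = config.max_coefficient

    elements = sorted(
        {e for ev in vectors for e in ev.counts}
        | {e for _, ev, _, _ in addables for e in ev.counts}
    )

    # conservation rows: elements + charge
    a_eq = np.zeros((len(elements) + 1, n_var))
    for i, (p, ev) in enumerate(zip(participants, vectors)):
        sign = 1 if p.stoichiometry > 0 else -1
        for j, e in enumerate(elements):
            a_eq[j, i] = sign * ev.counts.get(e, 0)
        a_eq[-1, i] = sign * ev.charge
    for z, (_, ev, side, _) in enumerate(addables):
        col = 2 * m + z
        for j, e in enumerate(elements):
            a_eq[j, col] = side * ev.counts.get(e, 0)
        a_eq[-1, col] = side * ev.charge

    # deviation rows: d_i >= |c_i - o_i|
    o = np.array([abs(p.stoichiometry) for p in participants])
    a_dev = np.zeros((2 * m, n_var))
    lb_dev = np.zeros(2 * m)
    for i in range(m):
        a_dev[2 * i, i] = -1.0      # d_i - c_i >= -o_i
        a_dev[2 * i, m + i] = 1.0
        lb_dev[2 * i] = -o[i]
        a_dev[2 * i + 1, i] = 1.0   # d_i + c_i >= o_i
        a_dev[2 * i + 1, m + i] = 1.0
        lb_dev[2 * i + 1] = o[i]

    obj = np.zeros(n_var)
    obj[:m] += _W_SUM
    obj[m:2 * m] = _W_DEV
    for z, (_, _, _, pref) in enumerate(addables):
        obj[2 * m + z] = _W_ADD + _W_PREF * pref + _W_SUM

    # weight-tier sanity for the configured bound (lexicographic exactness)
    n_species = len(config.addable_species)
    assert _W_DEV > _W_ADD * 2 * n_species * max_c + _W_PREF * 2 * \
        n_species * max_c * n_species + _W_SUM * (m + 2 * n_species) * max_c
    assert _W_ADD > _W_PREF * n_species + _W_SUM * (m + 2 * n_species) * max_c

    lower = np.concatenate(
        [np.ones(m), np.zeros(m), np.zeros(k)]
    )
    upper = np.concatenate(
        [np.full(m, max_c), np.full(m, np.inf), np.full(k, max_c)]
    )
    integrality = np.concatenate(
        [np.ones(m), np.zeros(m), np.ones(k)]
    )

    constraints = [LinearConstraint(a_eq, 0.0, 0.0)]
    if m:
        constraints.append(LinearConstraint(a_dev, lb_dev, np.inf))
    res = milp(
        c=obj,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lower, upper),
    )
    if not res.success:
        return BalanceResult(BalanceStatus.UNBALANCEABLE, participants, [])

    x = np.round(res.x).astype(int)
    new_participants: list[Participant] = []
    delta: list[tuple[str, int, int]] = []
    for i, p in enumerate(participants):
        sign = 1 if p.stoichiometry > 0 else -1
        new_s = sign * int(x[i])
        new_participants.append(
            Participant(p.chemical_id, new_s, p.role)
        )
        if new_s != p.stoichiometry:
            delta.append((p.chemical_id, p.stoichiometry, new_s))
    for z, (chem_id, _, side, _) in enumerate(addables):
        coef = int(x[2 * m + z])
        if coef > 0:
            new_participants.append(Participant(chem_id, side * coef))
            delta.append((chem_id, 0, side * coef))

    status = BalanceStatus.REBALANCED if delta else BalanceStatus.ALREADY_BALANCED
    return BalanceResult(status, new_participants, delta)
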