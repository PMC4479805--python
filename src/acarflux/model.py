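"""Core data structures for constraint-based (stoichiometric) metabolic models.

A :class:`MetabolicModel` holds metabolites, reactions with flux bounds and
GPR rules, a gene set, and an objective reaction — everything flux balance
analysis needs: the steady-state system ``S v = 0`` with ``lb <= v <= ub``.

Sign conventions follow standard COBRA practice: negative stoichiometric
coefficients are substrates, positive are products; exchange reactions are
written ``M[e] <=> (boundary)`` so that negative flux is uptake and positive
flux is secretion.  Fluxes are in mmol/gDCW/h (growth in 1/h).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .gpr import GPR

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelStructureError",
    "BalanceViolation",
    "BalanceReport",
    "build_stoichiometric_matrix",
    "check_balance",
    "evaluate_gpr",
    "apply_gene_deletion",
]

COMPARTMENTS = ("c", "e")

#: conventional default bounds when a model file does not state any
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)
DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)


class ModelStructureError(ValueError):
    """A structural invariant of the model is violated (dangling reference,
    duplicate id, malformed reaction)."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to count and may be empty when the
    composition is unknown (the published genome-scale model mixes curated
    and auto-generated entries); ``charge`` may likewise be None.
    """

    id: str
    name: str = ""
    formula: Dict[str, float] = field(default_factory=dict)
    charge: Optional[int] = None
    compartment: str = "c"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelStructureError(
                f"metabolite {self.id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )


@dataclass
class Reaction:
    """A (possibly pseudo-) reaction with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id to a signed real coefficient
    (negative = consumed).  ``is_exchange`` marks boundary pseudo-reactions
    with exactly one (extracellular) metabolite.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    gpr: GPR = field(default_factory=GPR.empty)
    subsystem: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelStructureError(
                f"exchange reaction {self.id!r} must involve exactly one "
                f"metabolite, got {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,  # immutable
            subsystem=self.subsystem,
            is_exchange=self.is_exchange,
        )


@dataclass
class MetabolicModel:
    """A full constraint-based model: metabolites, reactions, genes, objective."""

    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: Set[str] = field(default_factory=set)
    objective_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelStructureError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelStructureError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
            unknown_genes = rxn.gpr.genes - self.genes
            if unknown_genes:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} GPR references genes not in the "
                    f"model's gene set: {sorted(unknown_genes)}"
                )
        if self.objective_id is not None and self.objective_id not in set(rxn_ids):
            raise ModelStructureError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    def copy(self) -> "MetabolicModel":
        clone = MetabolicModel.__new__(MetabolicModel)
        clone.id = self.id
        clone.metabolites = [_copy.copy(m) for m in self.metabolites]
        for m in clone.metabolites:
            m.formula = dict(m.formula)
        clone.reactions = [r.copy() for r in self.reactions]
        clone.genes = set(self.genes)
        clone.objective_id = self.objective_id
        return clone


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> Tuple[np.ndarray, Dict[str, int], Dict[str, int]]:
    """Assemble the stoichiometric matrix S (metabolites x reactions).

    Returns ``(S, met_index, rxn_index)`` where the index maps give each
    id's row/column.  ``S[i, j]`` is the signed coefficient of metabolite i
    in reaction j; absent pairs are 0.
    """
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rxn in model.reactions:
        j = rxn_index[rxn.id]
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in met_index:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            S[met_index[met_id], j] = coeff
    return S, met_index, rxn_index


@dataclass
class BalanceViolation:
    reaction_id: str
    imbalance: Dict[str, float]  # element -> net production (should be 0)


@dataclass
class BalanceReport:
    """Outcome of elemental/charge balance checking.

    ``violations`` lists internal reactions whose element or charge totals
    do not cancel; ``skipped`` lists reactions touching a metabolite with
    unknown formula (they cannot be checked and are reported, not failed).
    """

    violations: List[BalanceViolation]
    skipped: List[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def check_balance(
    model: MetabolicModel,
    *,
    tol: float = 1e-9,
    biomass_id: str = "BIOMASS",
) -> BalanceReport:
    """Check elemental and charge balance of every internal reaction.

    Exchange reactions and the biomass pseudo-reaction are exempt (they
    cross the system boundary / drain many precursors by design).
    Metabolites with an unknown (empty) formula cause the reaction to be
    skipped and listed rather than flagged.
    """
    mets = {m.id: m for m in model.metabolites}
    violations: List[BalanceViolation] = []
    skipped: List[str] = []
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == biomass_id or rxn.id == model.objective_id:
            continue
        if any(not mets[mid].formula for mid in rxn.stoichiometry):
            skipped.append(rxn.id)
            continue
        net: Dict[str, float] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            for element, count in mets[met_id].formula.items():
                net[element] = net.get(element, 0.0) + coeff * count
        charges = [mets[mid].charge for mid in rxn.stoichiometry]
        if all(c is not None for c in charges):
            q = sum(
                coeff * mets[mid].charge  # type: ignore[operator]
                for mid, coeff in rxn.stoichiometry.items()
            )
            if abs(q) > tol:
                net["charge"] = q
        imbalance = {el: v for el, v in net.items() if abs(v) > tol}
        if imbalance:
            violations.append(BalanceViolation(rxn.id, imbalance))
    return BalanceReport(violations, skipped)


def evaluate_gpr(gpr: GPR, deleted: Iterable[str] = ()) -> bool:
    """True iff the reaction guarded by *gpr* remains catalysable when the
    genes in *deleted* are knocked out.  Empty GPR -> True."""
    return gpr.evaluate(deleted)


def apply_gene_deletion(
    model: MetabolicModel, deleted: Iterable[str]
) -> MetabolicModel:
    """Return a derived model with both bounds set to 0 for every reaction
    whose GPR evaluates False under the deletion.

    The original model is not modified.  Gene ids absent from the model are
    allowed and affect nothing.
    """
    deleted = frozenset(deleted)
    derived = model.copy()
    for rxn in derived.reactions:
        if rxn.gpr and not rxn.gpr.evaluate(deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return derived
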