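"""Single-gene and single-reaction deletion screens.

A target is essential when its deletion drives the optimized objective
below a threshold fraction of the wild type: grRatio = knockout objective
/ wild-type objective, essential iff grRatio < 1e-6 (the conventional
cut).  The wild-type optimum is solved once per screen so every grRatio
shares the same denominator.

Product essentiality uses the production objective (product exchange
maximized at a fixed growth rate, default 0 = pure capability), which
separates genes needed to *make* the product from genes needed to grow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .fba import FBAError, solve_fba
from .medium import MediumSpec, apply_medium
from .model import MetabolicModel, apply_gene_deletion

__all__ = [
    "ESSENTIALITY_THRESHOLD",
    "EssentialityResult",
    "single_gene_deletion",
    "single_reaction_deletion",
    "product_essential_genes",
    "essentiality_summary",
]

ESSENTIALITY_THRESHOLD = 1e-6


@dataclass
class EssentialityResult:
    target_id: str
    kind: str  # "gene" | "reaction"
    wild_type_objective: float
    knockout_objective: float
    gr_ratio: float
    essential: bool
    subsystems: Tuple[str, ...] = ()


def _gene_subsystems(model: MetabolicModel) -> Dict[str, Tuple[str, ...]]:
    out: Dict[str, set] = {g: set() for g in model.genes}
    for rxn in model.reactions:
        for g in rxn.gpr.genes:
            out[g].add(rxn.subsystem)
    return {g: tuple(sorted(s)) for g, s in out.items()}


def _wild_type(
    model: MetabolicModel, medium: Optional[MediumSpec], objective: Optional[str]
) -> float:
    sol = solve_fba(model, medium, objective=objective)
    if not sol.ok:
        raise FBAError(
            "wild-type objective could not be solved "
            f"(status {sol.status}); screen aborted before any deletion"
        )
    if sol.objective_value <= 0:
        raise FBAError(
            "wild-type objective is zero; essentiality ratios are undefined"
        )
    return sol.objective_value


def _result(
    target: str, kind: str, wt: float, ko: float,
    subsystems: Tuple[str, ...], threshold: float,
) -> EssentialityResult:
    ko = max(ko, 0.0)
    ratio = ko / wt
    return EssentialityResult(
        target_id=target, kind=kind, wild_type_objective=wt,
        knockout_objective=ko, gr_ratio=ratio,
        essential=ratio < threshold, subsystems=subsystems,
    )


def single_gene_deletion(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    objective: Optional[str] = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> List[EssentialityResult]:
    """Delete each gene alone and report grRatio against one shared
    wild-type solve.  Genes absent from every GPR are reported with
    grRatio 1 so the result count matches the model's gene set.

    The medium is applied once before the deletions, so a knockout of a
    medium-opened exchange is never silently re-opened.
    """
    constrained = apply_medium(model, medium) if medium is not None else model
    wt = _wild_type(constrained, None, objective)
    subsystems = _gene_subsystems(model)
    results = []
    for gene in sorted(model.genes):
        ko_model = apply_gene_deletion(constrained, {gene})
        if all(
            a.lower_bound == b.lower_bound and a.upper_bound == b.upper_bound
            for a, b in zip(constrained.reactions, ko_model.reactions)
        ):
            ko_value = wt  # deletion touches no reaction
        else:
            sol = solve_fba(ko_model, None, objective=objective)
            ko_value = sol.objective_value if sol.ok else 0.0
        results.append(
            _result(gene, "gene", wt, ko_value, subsystems[gene], threshold)
        )
    return results


def single_reaction_deletion(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    objective: Optional[str] = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> List[EssentialityResult]:
    """Constrain each reaction alone to zero flux and report grRatio."""
    constrained = apply_medium(model, medium) if medium is not None else model
    wt = _wild_type(constrained, None, objective)
    results = []
    for rxn in constrained.reactions:
        ko_model = constrained.copy()
        target = ko_model.reaction(rxn.id)
        target.lower_bound = 0.0
        target.upper_bound = 0.0
        sol = solve_fba(ko_model, None, objective=objective)
        ko_value = sol.objective_value if sol.ok else 0.0
        results.append(
            _result(rxn.id, "reaction", wt, ko_value, (rxn.subsystem,), threshold)
        )
    return results


def product_essential_genes(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    product_exchange: str,
    fixed_growth: float = 0.0,
    biomass_id: Optional[str] = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> List[EssentialityResult]:
    """Genes whose deletion abolishes maximal product formation.

    The objective is the product exchange with biomass fixed at
    ``fixed_growth`` (default 0: capability to produce at all).
    """
    biomass_id = biomass_id or model.objective_id
    rates = {biomass_id: fixed_growth} if biomass_id else None
    constrained = apply_medium(model, medium) if medium is not None else model
    wt_sol = solve_fba(
        constrained, None, objective=product_exchange, fixed_rates=rates
    )
    if not wt_sol.ok or (wt_sol.objective_value or 0.0) <= 0:
        raise FBAError(
            f"wild type cannot produce through {product_exchange!r} "
            "in this medium; product-essentiality undefined"
        )
    wt = wt_sol.objective_value
    subsystems = _gene_subsystems(model)
    results = []
    for gene in sorted(model.genes):
        ko_model = apply_gene_deletion(constrained, {gene})
        sol = solve_fba(
            ko_model, None, objective=product_exchange, fixed_rates=rates
        )
        ko_value = sol.objective_value if sol.ok else 0.0
        results.append(
            _result(gene, "gene", wt, ko_value, subsystems[gene], threshold)
        )
    return results


def essentiality_summary(
    results: Sequence[EssentialityResult],
) -> pd.DataFrame:
    """Per-subsystem counts and percentages of essential targets.

    A gene spanning several subsystems contributes fractionally to each,
    so the percentage column sums to 100 (when any target is essential).
    """
    weights: Dict[str, float] = {}
    totals: Dict[str, float] = {}
    for res in results:
        subs = res.subsystems or ("(none)",)
        w = 1.0 / len(subs)
        for s in subs:
            totals[s] = totals.get(s, 0.0) + w
            if res.essential:
                weights[s] = weights.get(s, 0.0) + w
    n_essential = sum(weights.values())
    rows = []
    for s in sorted(totals):
        count = weights.get(s, 0.0)
        rows.append(
            {
                "subsystem": s,
                "essential": count,
                "total": totals[s],
                "percent_of_essential": (
                    100.0 * count / n_essential if n_essential else 0.0
                ),
            }
        )
    return pd.DataFrame(rows, columns=[
        "subsystem", "essential", "total", "percent_of_essential",
    ])
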