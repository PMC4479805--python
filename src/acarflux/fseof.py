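"""Flux scanning based on enforced objective flux (FSEOF).

FSEOF nominates amplification (overexpression) targets: the product flux
is stepped up from zero toward its theoretical maximum while growth is
re-optimized at each step, and every reaction's flux trajectory across the
steps is classified as increased, decreased, unchanged or irregular.
Reactions whose flux rises with enforced production — and the genes behind
them via the GPR rules — are candidates whose overexpression should pull
flux toward the product.

Each step uses parsimonious tie-breaking (minimal total absolute flux at
the growth optimum): without it, alternate optima make the per-reaction
trajectories, and hence the classes, arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .fba import FBAError, solve_fba
from .medium import MediumSpec
from .model import MetabolicModel

__all__ = [
    "FSEOFProfile",
    "fseof_scan",
    "classify_profile",
    "amplification_targets",
]

CLASSIFICATIONS = ("increased", "decreased", "irregular", "unchanged")


@dataclass
class FSEOFProfile:
    """Flux trajectory of one reaction across the enforced-product steps."""

    reaction_id: str
    enforced: List[float]  # enforced product flux per step
    fluxes: List[float]
    classification: str
    genes: Tuple[str, ...]

    @property
    def relative_change(self) -> float:
        base = max(abs(self.fluxes[0]), 1e-12)
        return (self.fluxes[-1] - self.fluxes[0]) / base


def classify_profile(fluxes: Sequence[float], tol: Optional[float] = None) -> str:
    """Classify a flux trajectory.

    increased: every successive difference >= -tol and total change > tol;
    decreased: symmetric; unchanged: max |difference| <= tol; otherwise
    irregular.  Default tolerance scales with the mean flux magnitude.
    """
    if len(fluxes) < 3:
        raise ValueError("a profile needs at least 3 steps to classify")
    if tol is None:
        mean = sum(fluxes) / len(fluxes)
        tol = 1e-6 * max(1.0, abs(mean))
    diffs = [b - a for a, b in zip(fluxes, fluxes[1:])]
    total = fluxes[-1] - fluxes[0]
    if all(abs(d) <= tol for d in diffs):
        return "unchanged"
    if all(d >= -tol for d in diffs) and total > tol:
        return "increased"
    if all(d <= tol for d in diffs) and total < -tol:
        return "decreased"
    return "irregular"


def fseof_scan(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    product_exchange: str,
    n_steps: int = 10,
    fraction: float = 0.9,
    objective: Optional[str] = None,
    tol: Optional[float] = None,
) -> List[FSEOFProfile]:
    """Scan all reactions across enforced product-flux steps.

    The theoretical maximum product flux v_max is found first; step k then
    fixes the product flux at ``(k/n_steps) * fraction * v_max`` and
    maximizes growth with parsimonious tie-breaking.  The fraction keeps
    the scan away from the near-v_max region where growth becomes
    infeasible.
    """
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    objective = objective or model.objective_id
    vmax_sol = solve_fba(model, medium, objective=product_exchange)
    if not vmax_sol.ok or (vmax_sol.objective_value or 0.0) <= 1e-9:
        raise FBAError(
            f"product {product_exchange!r} is not producible in this medium"
        )
    vmax = vmax_sol.objective_value
    enforced = [(k / n_steps) * fraction * vmax for k in range(1, n_steps + 1)]
    trajectories: Dict[str, List[float]] = {r.id: [] for r in model.reactions}
    for target in enforced:
        sol = solve_fba(
            model, medium, objective=objective,
            fixed_rates={product_exchange: target}, parsimonious=True,
        )
        if not sol.ok:
            raise FBAError(
                f"growth optimization infeasible at enforced product flux "
                f"{target:g}; lower the fraction ({fraction})"
            )
        for rxn_id in trajectories:
            trajectories[rxn_id].append(sol.fluxes[rxn_id])
    profiles = []
    for rxn in model.reactions:
        fluxes = trajectories[rxn.id]
        profiles.append(
            FSEOFProfile(
                reaction_id=rxn.id,
                enforced=list(enforced),
                fluxes=fluxes,
                classification=classify_profile(fluxes, tol),
                genes=tuple(sorted(rxn.gpr.genes)),
            )
        )
    return profiles


def amplification_targets(
    profiles: Sequence[FSEOFProfile],
    exclude_reactions: Set[str] = frozenset(),
) -> List[FSEOFProfile]:
    """Increased-class profiles ranked by relative flux increase.

    ``exclude_reactions`` typically holds the product pathway itself and
    the product exchange (enforced by construction).  Reactions with an
    empty GPR are kept in the ranking with no gene attached.
    """
    hits = [
        p for p in profiles
        if p.classification == "increased" and p.reaction_id not in exclude_reactions
    ]
    return sorted(hits, key=lambda p: (-p.relative_change, p.reaction_id))


def ranked_genes(targets: Sequence[FSEOFProfile]) -> List[str]:
    """Genes of ranked target reactions, first occurrence wins."""
    seen: List[str] = []
    for profile in targets:
        for gene in profile.genes:
            if gene not in seen:
                seen.append(gene)
    return seen
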