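"""Flux balance analysis: the LP engine and the simulation modes built on it.

FBA maximizes (or minimizes) the flux through an objective reaction subject
to the steady-state constraint ``S v = 0`` and the flux bounds, with medium
uptake caps applied to the exchange reactions.  On top of the plain solve
this module provides the workflows used to interrogate a producer strain:

* :func:`simulate_growth` — maximal growth rate under fitted uptake rates;
* :func:`simulate_production` — maximal product secretion at fixed growth;
* :func:`robustness_scan` — objective as a function of one constrained flux
  (e.g. acarbose production versus oxygen uptake rate);
* :func:`pathway_flux_ratio` — flux split between two pathway entries
  (e.g. pentose phosphate pathway versus glycolysis).

Alternate optima are endemic in FBA; objective values are the contract
here, and whenever individual fluxes matter a parsimonious tie-break
(secondary minimization of total absolute flux) is available and used by
the downstream scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .medium import MediumSpec, apply_medium
from .model import MetabolicModel, build_stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "RobustnessCurve",
    "FBAError",
    "UndefinedFluxRatioError",
    "solve_fba",
    "simulate_growth",
    "simulate_production",
    "robustness_scan",
    "pathway_flux_ratio",
]

#: growth/no-growth call threshold (1/h), same scale as the essentiality cut
GROWTH_THRESHOLD = 1e-6


class FBAError(RuntimeError):
    """Raised when a simulation cannot produce the requested quantity."""


class UndefinedFluxRatioError(ZeroDivisionError):
    """Raised when a pathway flux ratio has zero denominator flux."""


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``objective_value`` is in 1/h when the objective is the biomass
    reaction, mmol/gDCW/h otherwise.  ``fluxes`` is empty unless the
    status is optimal.
    """

    status: str  # optimal | infeasible | unbounded | failed
    objective_value: Optional[float] = None
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class RobustnessCurve:
    """Objective value as a function of one reaction's fixed flux."""

    reaction_id: str
    grid: List[float]
    values: List[Optional[float]]
    statuses: List[str]

    def peak(self) -> tuple[float, float]:
        """(grid value, objective) at the maximal feasible objective."""
        best = None
        for g, v in zip(self.grid, self.values):
            if v is not None and (best is None or v > best[1]):
                best = (g, v)
        if best is None:
            raise FBAError(f"no feasible point on the {self.reaction_id} grid")
        return best


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}


def _prepare(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    fixed_rates: Optional[Mapping[str, float]],
) -> MetabolicModel:
    m = apply_medium(model, medium) if medium is not None else model.copy()
    if fixed_rates:
        for rxn_id, value in fixed_rates.items():
            rxn = m.reaction(rxn_id)  # KeyError if absent
            rxn.lower_bound = value
            rxn.upper_bound = value
    return m


def solve_fba(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    objective: Optional[str] = None,
    direction: str = "max",
    fixed_rates: Optional[Mapping[str, float]] = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Solve the FBA linear program.

    Parameters
    ----------
    objective
        Reaction id to optimize; defaults to ``model.objective_id``.
    direction
        ``"max"`` or ``"min"``.
    fixed_rates
        Signed equality constraints ``lb = ub = value`` (model sign
        convention: negative exchange flux is uptake).
    parsimonious
        After optimizing, minimize total absolute flux at the fixed
        optimum (pFBA) to stabilize the reported flux vector.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    objective = objective or model.objective_id
    if objective is None:
        raise FBAError("no objective reaction given and model has none")
    m = _prepare(model, medium, fixed_rates)
    S, _, rxn_index = build_stoichiometric_matrix(m)
    if objective not in rxn_index:
        raise KeyError(f"objective reaction {objective!r} not in model")
    n = S.shape[1]
    bounds = [(r.lower_bound, r.upper_bound) for r in m.reactions]
    c = np.zeros(n)
    c[rxn_index[objective]] = -1.0 if direction == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_id=objective)
    v = res.x
    opt = float(v[rxn_index[objective]])
    if parsimonious:
        v = _parsimonious_fluxes(S, bounds, rxn_index[objective], opt, v)
    fluxes = {rxn_id: float(v[j]) for rxn_id, j in rxn_index.items()}
    return FluxSolution("optimal", opt, fluxes, objective)


def _parsimonious_fluxes(
    S: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    obj_col: int,
    opt: float,
    fallback: np.ndarray,
) -> np.ndarray:
    """Minimize sum |v| subject to S v = 0, bounds, and v[obj] = opt.

    Uses auxiliary variables u >= |v|; returns the original vector if the
    secondary LP fails numerically.
    """
    n = S.shape[1]
    obj_row = np.zeros(n)
    obj_row[obj_col] = 1.0
    A_eq = np.vstack([S, obj_row])
    b_eq = np.append(np.zeros(S.shape[0]), opt)
    # variables [v, u]; constraints v - u <= 0 and -v - u <= 0
    eye = np.eye(n)
    A_ub = np.block([[eye, -eye], [-eye, -eye]])
    b_ub = np.zeros(2 * n)
    A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
    u_max = max(max(abs(lo), abs(hi)) for lo, hi in bounds)
    var_bounds = list(bounds) + [(0.0, u_max)] * n
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq,
        bounds=var_bounds, method="highs",
    )
    if res.status != 0:
        return fallback
    return res.x[:n]


def simulate_growth(
    model: MetabolicModel,
    medium: Optional[MediumSpec] = None,
    fixed_rates: Optional[Mapping[str, float]] = None,
    biomass_id: Optional[str] = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Maximal growth rate under equality-constrained exchange rates.

    ``fixed_rates`` uses the model sign convention (uptake negative); the
    medium's own ``fixed`` entries already encode uptake as positive caps.
    """
    biomass_id = biomass_id or model.objective_id
    if biomass_id is None:
        raise FBAError("no biomass reaction identified")
    return solve_fba(
        model, medium, objective=biomass_id, direction="max",
        fixed_rates=fixed_rates, parsimonious=parsimonious,
    )


def simulate_production(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    fixed_growth: float,
    product_exchange: str,
    biomass_id: Optional[str] = None,
    fixed_rates: Optional[Mapping[str, float]] = None,
    parsimonious: bool = False,
) -> FluxSolution:
    """Maximal product secretion with biomass fixed at *fixed_growth* (1/h)."""
    biomass_id = biomass_id or model.objective_id
    if biomass_id is None:
        raise FBAError("no biomass reaction identified")
    rates: Dict[str, float] = dict(fixed_rates or {})
    rates[biomass_id] = fixed_growth
    sol = solve_fba(
        model, medium, objective=product_exchange, direction="max",
        fixed_rates=rates, parsimonious=parsimonious,
    )
    if sol.status == "infeasible":
        raise FBAError(
            f"growth rate {fixed_growth} /h is infeasible under the given "
            f"medium; cannot evaluate production through {product_exchange}"
        )
    return sol


def robustness_scan(
    model: MetabolicModel,
    medium: Optional[MediumSpec],
    scanned: str,
    grid: Sequence[float],
    objective: Optional[str] = None,
    fixed_rates: Optional[Mapping[str, float]] = None,
) -> RobustnessCurve:
    """Re-optimize the objective with the scanned reaction fixed at each
    grid value.  Infeasible points are recorded as such (value None)."""
    grid = list(grid)
    if not grid:
        raise ValueError("robustness grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("robustness grid must be strictly increasing")
    model.reaction(scanned)  # KeyError early if absent
    values: List[Optional[float]] = []
    statuses: List[str] = []
    for g in grid:
        rates = dict(fixed_rates or {})
        rates[scanned] = g
        sol = solve_fba(model, medium, objective=objective, fixed_rates=rates)
        values.append(sol.objective_value if sol.ok else None)
        statuses.append(sol.status)
    return RobustnessCurve(scanned, grid, values, statuses)


def pathway_flux_ratio(
    solution: FluxSolution,
    pathway_a: Iterable[str],
    pathway_b: Iterable[str],
) -> float:
    """Ratio of total absolute flux through the designated entry reactions
    of pathway A over pathway B (e.g. PPP over glycolysis)."""
    if not solution.ok:
        raise FBAError("pathway_flux_ratio requires an optimal solution")
    a = sum(abs(solution.fluxes[r]) for r in pathway_a)
    b = sum(abs(solution.fluxes[r]) for r in pathway_b)
    if b == 0:
        raise UndefinedFluxRatioError(
            "denominator pathway carries zero flux; ratio undefined"
        )
    return a / b
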