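"""Independent oracles used by the test suite.

These deliberately avoid the package's own solution paths: the LP optimum
is recomputed by exhaustive vertex enumeration of the flux polytope, GPR
evaluation by Python's own boolean operators on the rule string, and
elemental balance by brute-force per-column summation over the
stoichiometric matrix.
"""

from __future__ import annotations

import re
from itertools import combinations, product
from typing import Dict, Iterable, Optional

import numpy as np

from acarflux.medium import MediumSpec, apply_medium
from acarflux.model import MetabolicModel, build_stoichiometric_matrix


def vertex_enumeration_optimum(
    model: MetabolicModel,
    objective: str,
    medium: Optional[MediumSpec] = None,
    direction: str = "max",
    tol: float = 1e-8,
) -> float:
    """Optimal objective over {S v = 0, lb <= v <= ub} by enumerating the
    vertices of the polytope (fix d = n - rank(S) variables at a bound,
    solve the rest, keep feasible points).  Exponential; toy models only.
    """
    m = apply_medium(model, medium) if medium is not None else model
    S, _, rxn_index = build_stoichiometric_matrix(m)
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in m.reactions])
    ub = np.array([r.upper_bound for r in m.reactions])
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    j_obj = rxn_index[objective]
    best = None
    for fixed_vars in combinations(range(n), d):
        free_vars = [j for j in range(n) if j not in fixed_vars]
        S_free = S[:, free_vars]
        if free_vars and np.linalg.matrix_rank(S_free) < len(free_vars):
            continue  # not a basic solution; some other subset covers it
        for corners in product(*[(lb[j], ub[j]) for j in fixed_vars]):
            v = np.zeros(n)
            for j, val in zip(fixed_vars, corners):
                v[j] = val
            rhs = -S[:, fixed_vars] @ np.array(corners) if fixed_vars else np.zeros(S.shape[0])
            if free_vars:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free_vars] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = v[j_obj]
            if best is None or (value > best if direction == "max" else value < best):
                best = value
    if best is None:
        raise RuntimeError("no feasible vertex found")
    return float(best)


_GENE_TOKEN = re.compile(r"[A-Za-z0-9_.:\-]+")


def gpr_truth_oracle(rule: str, deleted: Iterable[str]) -> bool:
    """Evaluate a GPR string with Python's own and/or/parentheses.

    Gene tokens are substituted by True/False literals and the result is
    eval'd — a route fully independent of the package's parser.
    """
    deleted = set(deleted)

    def sub(match: re.Match) -> str:
        tok = match.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return str(tok not in deleted)

    expr = _GENE_TOKEN.sub(sub, rule)
    return bool(eval(expr))  # noqa: S307 - test oracle on generated input


def element_balance_by_columns(model: MetabolicModel) -> Dict[str, Dict[str, float]]:
    """Net element production per internal reaction, recomputed from the
    stoichiometric matrix column by column."""
    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    mets = {m.id: m for m in model.metabolites}
    out: Dict[str, Dict[str, float]] = {}
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.objective_id:
            continue
        if any(not mets[mid].formula for mid in rxn.stoichiometry):
            continue
        col = S[:, rxn_index[rxn.id]]
        net: Dict[str, float] = {}
        for met_id, i in met_index.items():
            if col[i] == 0:
                continue
            for element, count in mets[met_id].formula.items():
                net[element] = net.get(element, 0.0) + col[i] * count
        out[rxn.id] = {e: v for e, v in net.items() if abs(v) > 1e-9}
    return out


def to_cobra(model: MetabolicModel, medium: Optional[MediumSpec] = None):
    """Convert to a cobrapy model (used as an independent FBA cross-check)."""
    import cobra

    m = apply_medium(model, medium) if medium is not None else model
    cm = cobra.Model(m.id)
    cobra_mets = {}
    for met in m.metabolites:
        cid = met.id.replace("[", "_").rstrip("]")
        cobra_mets[met.id] = cobra.Metabolite(cid, compartment=met.compartment)
    for rxn in m.reactions:
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites(
            {cobra_mets[mid]: coeff for mid, coeff in rxn.stoichiometry.items()}
        )
    cm.objective = m.objective_id
    return cm
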