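"""Qualitative sole-carbon / sole-nitrogen source growth screens.

Each candidate substrate is opened as the only source of its nutrient
class in a minimal medium (the base medium supplies everything else) and
growth is called positive when the optimized growth rate exceeds the
standard threshold.  Calls are compared against an observed (+/-) table
to give a match fraction, the way model reconstructions are validated
against plate growth data.

The uptake cap for the tested substrate defaults to 10 mmol/gDCW/h;
qualitative calls are cap-invariant for any positive cap, which the test
suite asserts by screening at two caps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .fba import GROWTH_THRESHOLD, solve_fba
from .medium import MediumSpec
from .model import MetabolicModel

__all__ = ["PhenotypeCall", "sole_source_screen", "compare_to_observed"]


@dataclass
class PhenotypeCall:
    substrate: str  # exchange reaction id
    role: str  # "carbon" | "nitrogen"
    predicted: bool
    mu: float
    observed: Optional[bool] = None
    note: str = ""


def sole_source_screen(
    model: MetabolicModel,
    base_medium: MediumSpec,
    substrates: Sequence[str],
    role: str,
    uptake_cap: float = 10.0,
    objective: Optional[str] = None,
) -> List[PhenotypeCall]:
    """Screen each substrate as the sole source of its nutrient class.

    ``base_medium`` must already exclude every exchange of the tested
    class (for a carbon screen: nitrogen/phosphate/oxygen open, no carbon
    source).  A substrate whose exchange is missing from the model is
    recorded as predicted-negative with a note rather than failing, so a
    screen over a printed substrate table survives incomplete models.
    """
    if role not in ("carbon", "nitrogen"):
        raise ValueError(f"role must be 'carbon' or 'nitrogen', got {role!r}")
    exchange_ids = {r.id for r in model.exchanges}
    calls = []
    for substrate in substrates:
        if substrate not in exchange_ids:
            calls.append(
                PhenotypeCall(substrate, role, False, 0.0, note="no exchange")
            )
            continue
        medium = base_medium.with_uptake(**{substrate: uptake_cap})
        sol = solve_fba(model, medium, objective=objective)
        mu = sol.objective_value if sol.ok else 0.0
        calls.append(PhenotypeCall(substrate, role, mu > GROWTH_THRESHOLD, mu))
    return calls


def compare_to_observed(
    calls: Sequence[PhenotypeCall],
    observed: Mapping[str, bool],
) -> Tuple[float, List[PhenotypeCall]]:
    """Match fraction against observed growth calls plus the discrepancies.

    Raises if the substrate sets differ — a silent partial comparison
    would inflate the match fraction.
    """
    call_ids = {c.substrate for c in calls}
    if call_ids != set(observed):
        missing = sorted(set(observed) ^ call_ids)
        raise ValueError(f"substrate mismatch between calls and table: {missing}")
    matches = 0
    discrepancies = []
    for call in calls:
        call.observed = observed[call.substrate]
        if call.predicted == call.observed:
            matches += 1
        else:
            discrepancies.append(call)
    return matches / len(calls), discrepancies
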