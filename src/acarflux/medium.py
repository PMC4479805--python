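"""Growth-medium specifications as exchange-reaction constraints.

A :class:`MediumSpec` encodes a medium recipe the way constraint-based
models consume it: a map from exchange-reaction id to the maximum uptake
rate allowed (mmol/gDCW/h, given as positive numbers), plus optional fixed
uptake rates (equality constraints, e.g. a fitted maltose uptake rate).

Applying a medium closes every exchange to uptake first and then opens the
listed ones, so an empty medium means "nothing can be taken up".  Secretion
bounds are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .model import MetabolicModel

__all__ = ["MediumSpec", "apply_medium"]


@dataclass
class MediumSpec:
    """Uptake caps and fixed uptake rates for exchange reactions.

    Rates are positive numbers in mmol/gDCW/h; internally uptake is a
    negative exchange flux, so a cap of ``c`` becomes lower bound ``-c``
    and a fixed rate ``r`` becomes ``lb = ub = -r``.
    """

    name: str = "medium"
    uptake: Dict[str, float] = field(default_factory=dict)
    fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.uptake, self.fixed):
            for rxn_id, rate in table.items():
                if rate < 0:
                    raise ValueError(
                        f"medium {self.name!r}: rate for {rxn_id} must be "
                        f">= 0, got {rate}"
                    )

    def with_uptake(self, **caps: float) -> "MediumSpec":
        """A copy with additional/overridden uptake caps."""
        merged = dict(self.uptake)
        merged.update(caps)
        return MediumSpec(self.name, merged, dict(self.fixed))

    def without(self, *rxn_ids: str) -> "MediumSpec":
        """A copy with the given exchanges removed (closed to uptake)."""
        drop = set(rxn_ids)
        return MediumSpec(
            self.name,
            {k: v for k, v in self.uptake.items() if k not in drop},
            {k: v for k, v in self.fixed.items() if k not in drop},
        )


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of *model* constrained to *medium*.

    All exchange reactions are first closed to uptake (lower bound raised
    to 0); exchanges listed in the medium then get ``lb = -cap`` (uptake
    caps) or ``lb = ub = -rate`` (fixed rates).
    """
    constrained = model.copy()
    exchange_ids = {r.id for r in constrained.exchanges}
    unknown = (set(medium.uptake) | set(medium.fixed)) - exchange_ids
    if unknown:
        raise KeyError(
            f"medium {medium.name!r} references exchanges not in the model: "
            f"{sorted(unknown)}"
        )
    for rxn in constrained.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.fixed:
            rate = medium.fixed[rxn.id]
            rxn.lower_bound = -rate
            rxn.upper_bound = -rate
        elif rxn.id in medium.uptake:
            rxn.lower_bound = -medium.uptake[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return constrained
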