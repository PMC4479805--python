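"""Biomass-equation construction from macromolecular composition.

The biomass pseudo-reaction drains monomer precursors in growth-rate-
proportional amounts.  Its stoichiometric coefficients follow from (i) the
macromolecular mass fractions of the dry cell (g/gDCW), (ii) the monomer
mole fractions within each macromolecule class, and (iii) the residue
molar masses of the monomers in polymerized form (water of condensation
removed), so that one flux unit of the reaction consumes exactly 1 g of
dry-cell material:

    coefficient_i = 1000 * f_m * x_i / M_bar_m   [mmol/gDCW]

with ``M_bar_m = sum_i x_i * M_i`` the mean residue mass of class m.

The default composition for the acarbose producer *Actinoplanes* sp.
SE50/110 is 58% protein, 1% DNA, 11% RNA, 5% lipids, 22% cell wall and
3% small molecules, with DNA monomer fractions derived from the genomic
G+C content (71.3%) and an RNA pool split 5/75/20 into mRNA/rRNA/tRNA.
The monomer mole-fraction tables shipped here are editable templates
(documented, synthetic defaults), not measured profiles; composition is
treated as independent of the cultivation environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

from .model import Reaction

__all__ = [
    "BiomassComposition",
    "CompositionError",
    "dna_monomer_fractions",
    "build_biomass_reaction",
    "reconstructed_mass",
    "default_composition",
]

#: macromolecule classes recognized in a composition
CLASSES = ("protein", "DNA", "RNA", "lipid", "cell_wall", "small_molecules")

_SUM_TOL = 1e-6
MASS_TOL = 1e-3  # grams, on the 1 g reconstruction check


class CompositionError(ValueError):
    """Invalid biomass composition (fractions not summing to 1, missing
    residue mass, out-of-range G+C content)."""


# monomer table: monomer id -> (mole fraction, residue molar mass g/mol)
MonomerTable = Dict[str, Tuple[float, float]]


@dataclass
class BiomassComposition:
    """Macromolecular mass fractions plus per-class monomer tables.

    ``energy_requirement`` is the growth-associated ATP demand (GAM) in
    mmol ATP per gDCW, added as ATP + H2O -> ADP + Pi to the reaction.
    """

    mass_fractions: Dict[str, float]
    monomer_tables: Dict[str, MonomerTable]
    gc_content: float = 0.713
    rna_class_split: Dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.05, "rRNA": 0.75, "tRNA": 0.20}
    )
    energy_requirement: float = 40.0

    def validate(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(
                f"macromolecular mass fractions sum to {total}, expected 1"
            )
        if any(f < 0 for f in self.mass_fractions.values()):
            raise CompositionError("mass fractions must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise CompositionError(
                f"G+C content must lie in (0, 1), got {self.gc_content}"
            )
        for cls, frac in self.mass_fractions.items():
            if frac == 0:
                continue
            table = self.monomer_tables.get(cls)
            if not table:
                raise CompositionError(f"no monomer table for class {cls!r}")
            fsum = sum(x for x, _ in table.values())
            if abs(fsum - 1.0) > _SUM_TOL:
                raise CompositionError(
                    f"monomer fractions of class {cls!r} sum to {fsum}, "
                    "expected 1"
                )
            for monomer, (_, mass) in table.items():
                if not mass or mass <= 0:
                    raise CompositionError(
                        f"missing/invalid residue mass for {monomer!r} "
                        f"in class {cls!r}"
                    )


def dna_monomer_fractions(gc: float) -> Dict[str, float]:
    """Mole fractions of the four DNA monomers from the G+C content.

    Base pairing makes dGMP and dCMP each gc/2 and dAMP and dTMP each
    (1-gc)/2; the purine fraction (dAMP+dGMP) is always one half.
    """
    if not 0.0 < gc < 1.0:
        raise CompositionError(f"G+C content must lie in (0, 1), got {gc}")
    return {
        "dAMP": (1.0 - gc) / 2.0,
        "dTMP": (1.0 - gc) / 2.0,
        "dGMP": gc / 2.0,
        "dCMP": gc / 2.0,
    }


def build_biomass_reaction(
    comp: BiomassComposition,
    reaction_id: str = "BIOMASS",
    compartment_suffix: str = "[c]",
    biomass_metabolite: str | None = "biomass[c]",
) -> Reaction:
    """Build the biomass pseudo-reaction (coefficients in mmol/gDCW).

    Consumes each monomer at ``1000 * f_m * x_i / M_bar_m`` plus the GAM
    ATP term; produces one unit of ``biomass_metabolite`` (omit by passing
    None).  Metabolite ids are ``<monomer id><compartment_suffix>``.
    """
    comp.validate()
    stoich: Dict[str, float] = {}
    for cls, f_m in comp.mass_fractions.items():
        if f_m == 0:
            continue
        table = comp.monomer_tables[cls]
        mean_mass = sum(x * m for x, m in table.values())
        for monomer, (x_i, _) in table.items():
            if x_i == 0:
                continue
            met = monomer + compartment_suffix
            stoich[met] = stoich.get(met, 0.0) - 1000.0 * f_m * x_i / mean_mass
    gam = comp.energy_requirement
    if gam:
        for met, coeff in (
            ("atp", -gam), ("h2o", -gam), ("adp", gam), ("pi", gam),
        ):
            key = met + compartment_suffix
            stoich[key] = stoich.get(key, 0.0) + coeff
    if biomass_metabolite is not None:
        stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        name="biomass equation",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass",
    )


def reconstructed_mass(
    reaction: Reaction,
    comp: BiomassComposition,
    compartment_suffix: str = "[c]",
) -> float:
    """Grams of monomer residue mass consumed per unit biomass flux.

    Independent check of mass conservation: should be 1 g +- 1e-3 for any
    valid composition (GAM and the biomass product are excluded).
    """
    masses: Dict[str, float] = {}
    for table in comp.monomer_tables.values():
        for monomer, (_, m) in table.items():
            masses[monomer + compartment_suffix] = m
    total = 0.0
    for met, coeff in reaction.stoichiometry.items():
        if coeff < 0 and met in masses:
            total += -coeff * masses[met] / 1000.0
    return total


# ---------------------------------------------------------------------------
# default (template) composition
# ---------------------------------------------------------------------------

#: residue molar masses, g/mol, polymerized form (monomer minus water)
AMINO_ACID_RESIDUE_MASS = {
    "ala": 71.08, "arg": 156.19, "asn": 114.10, "asp": 115.09,
    "cys": 103.14, "gln": 128.13, "glu": 129.12, "gly": 57.05,
    "his": 137.14, "ile": 113.16, "leu": 113.16, "lys": 128.17,
    "met": 131.19, "phe": 147.18, "pro": 97.12, "ser": 87.08,
    "thr": 101.10, "trp": 186.21, "tyr": 163.18, "val": 99.13,
}

#: template protein mole fractions (synthetic, editable; the measured
#: profile of the organism is not public)
AMINO_ACID_TEMPLATE_FRACTIONS = {
    "ala": 0.110, "arg": 0.055, "asn": 0.040, "asp": 0.050,
    "cys": 0.010, "gln": 0.040, "glu": 0.055, "gly": 0.095,
    "his": 0.018, "ile": 0.050, "leu": 0.085, "lys": 0.055,
    "met": 0.025, "phe": 0.035, "pro": 0.045, "ser": 0.050,
    "thr": 0.050, "trp": 0.012, "tyr": 0.025, "val": 0.095,
}

DNA_RESIDUE_MASS = {"dAMP": 313.21, "dTMP": 304.20, "dGMP": 329.21, "dCMP": 289.18}
RNA_RESIDUE_MASS = {"AMP": 329.21, "UMP": 306.17, "GMP": 345.21, "CMP": 305.18}


def default_composition(
    gc_content: float = 0.713, energy_requirement: float = 40.0
) -> BiomassComposition:
    """The default composition: measured class fractions of the organism
    (58/1/11/5/22/3 %), DNA monomers from the genomic G+C content, and
    template monomer tables for the classes whose measured profiles are
    only in non-public supplements.  Lipid, cell-wall and small-molecule
    pools are lumped single precursors with representative residue masses
    (synthetic templates, following the convention of adopting such data
    from related actinomycetes)."""
    dna_frac = dna_monomer_fractions(gc_content)
    # template RNA monomer fractions re-use the genomic G+C as a proxy for
    # the stable-RNA base composition
    rna_frac = {
        "AMP": (1.0 - gc_content) / 2.0,
        "UMP": (1.0 - gc_content) / 2.0,
        "GMP": gc_content / 2.0,
        "CMP": gc_content / 2.0,
    }
    tables: Dict[str, MonomerTable] = {
        "protein": {
            aa: (AMINO_ACID_TEMPLATE_FRACTIONS[aa], AMINO_ACID_RESIDUE_MASS[aa])
            for aa in sorted(AMINO_ACID_RESIDUE_MASS)
        },
        "DNA": {m: (dna_frac[m], DNA_RESIDUE_MASS[m]) for m in sorted(dna_frac)},
        "RNA": {m: (rna_frac[m], RNA_RESIDUE_MASS[m]) for m in sorted(rna_frac)},
        "lipid": {"lipid_precursor": (1.0, 700.0)},
        "cell_wall": {"cell_wall_unit": (1.0, 950.0)},
        "small_molecules": {"small_molecule_pool": (1.0, 350.0)},
    }
    comp = BiomassComposition(
        mass_fractions={
            "protein": 0.58, "DNA": 0.01, "RNA": 0.11,
            "lipid": 0.05, "cell_wall": 0.22, "small_molecules": 0.03,
        },
        monomer_tables=tables,
        gc_content=gc_content,
        energy_requirement=energy_requirement,
    )
    comp.validate()
    return comp
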