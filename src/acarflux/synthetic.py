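"""Deterministic generators for test models with known ground truth.

Three families:

* :func:`make_linear_chain` — a chain of lossy conversion steps whose FBA
  optimum has the closed form ``uptake_cap * yield**n``;
* :func:`make_branched_tradeoff` — growth and product competing linearly
  for one substrate, with a closed-form production/growth trade-off;
* :func:`make_mini_acb` — a ~30-reaction cell emulating the architecture
  of the acarbose producer's network: maltose uptake, a glycolysis/pentose-
  phosphate split (the PPP supplies sedoheptulose 7-phosphate, the C7-
  cyclitol precursor, and NADPH), a glutamate node feeding both biomass
  and the glutamate-dependent aminotransferase of the product pathway,
  oxygen-coupled ATP generation that makes product formation a unimodal
  function of the oxygen uptake rate, a dTDP-aminosugar branch condensed
  with the cyclitol into the exported product, and a TreY-like byproduct
  branch off the phosphorylated product precursor.

All generators are pure functions of their arguments (no randomness), so
the same parameters always yield byte-identical models.  The mini model's
stoichiometry uses simplified elemental bookkeeping (C/H/O/N/P plus opaque
carrier cores A, D, Q, T for the adenosine, NAD, NADP and dTDP moieties);
every internal reaction is exactly element-balanced.  All coefficients are
synthetic package constants, not measurements.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .gpr import GPR
from .io import parse_formula
from .medium import MediumSpec
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "make_linear_chain",
    "make_branched_tradeoff",
    "make_mini_acb",
    "mini_acb_media",
    "MINI_ACB_PRODUCT_GENES",
    "MINI_ACB_TREY_GENE",
]


def _met(met_id: str, name: str = "", formula: str = "") -> Metabolite:
    base, comp = met_id[:-3], met_id[-2]
    return Metabolite(
        id=met_id, name=name or base, formula=parse_formula(formula),
        charge=0 if formula else None, compartment=comp,
    )


def _rxn(
    rxn_id: str,
    stoich: Dict[str, float],
    lb: float = 0.0,
    ub: float = 1000.0,
    gpr: str = "",
    subsystem: str = "",
    name: str = "",
    exchange: bool = False,
) -> Reaction:
    return Reaction(
        id=rxn_id, name=name or rxn_id, stoichiometry=dict(stoich),
        lower_bound=lb, upper_bound=ub, gpr=GPR.parse(gpr),
        subsystem=subsystem, is_exchange=exchange,
    )


# ---------------------------------------------------------------------------
# linear chain
# ---------------------------------------------------------------------------

def make_linear_chain(
    n_steps: int, yield_per_step: float, uptake_cap: float
) -> MetabolicModel:
    """Chain of ``n_steps`` irreversible conversions, each with fractional
    yield; the FBA optimum is analytically ``uptake_cap * yield**n``.

    Each step carries a single gene ``g1..gn``, so the sole gene of any
    step is growth-essential.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < yield_per_step <= 1.0:
        raise ValueError("yield_per_step must lie in (0, 1]")
    if uptake_cap < 0:
        raise ValueError("uptake_cap must be >= 0")
    mets = [_met("sub[e]", "substrate")]
    rxns = [_rxn("EX_sub", {"sub[e]": -1.0}, lb=-uptake_cap, exchange=True,
                 subsystem="Exchange")]
    genes = set()
    prev = "sub[e]"
    for i in range(1, n_steps + 1):
        out = "bio[e]" if i == n_steps else f"x{i}[c]"
        mets.append(_met(out))
        gene = f"g{i}"
        genes.add(gene)
        rxns.append(
            _rxn(f"R{i}", {prev: -1.0, out: yield_per_step}, gpr=gene,
                 subsystem="Chain")
        )
        prev = out
    rxns.append(_rxn("EX_bio", {"bio[e]": -1.0}, exchange=True,
                     subsystem="Exchange"))
    return MetabolicModel(
        id="chain_toy", metabolites=mets, reactions=rxns, genes=genes,
        objective_id="EX_bio",
    )


# ---------------------------------------------------------------------------
# branched trade-off
# ---------------------------------------------------------------------------

def make_branched_tradeoff(
    substrate_cap: float = 10.0,
    biomass_yield: float = 0.5,
    product_yield: float = 0.3,
) -> MetabolicModel:
    """Biomass and product competing linearly for one substrate.

    Closed forms: ``mu_max = substrate_cap * biomass_yield`` and, at fixed
    growth mu, ``max product = product_yield * (substrate_cap - mu /
    biomass_yield)``.  Substrate enters through a redundant pair of
    transporters (genes gT1/gT2), so deleting either one is neutral.
    """
    if biomass_yield <= 0 or product_yield <= 0:
        raise ValueError("yields must be > 0")
    mets = [
        _met("sub[e]", "substrate"), _met("s[c]", "internal substrate"),
        _met("bio[e]", "biomass"), _met("prod[e]", "product"),
    ]
    rxns = [
        _rxn("EX_sub", {"sub[e]": -1.0}, lb=-substrate_cap, exchange=True,
             subsystem="Exchange"),
        _rxn("T1", {"sub[e]": -1.0, "s[c]": 1.0}, gpr="gT1",
             subsystem="Transport"),
        _rxn("T2", {"sub[e]": -1.0, "s[c]": 1.0}, gpr="gT2",
             subsystem="Transport"),
        _rxn("BIOMASS", {"s[c]": -1.0 / biomass_yield, "bio[e]": 1.0},
             gpr="gB", subsystem="Biomass", name="growth"),
        _rxn("PRODUCT", {"s[c]": -1.0 / product_yield, "prod[e]": 1.0},
             gpr="gP", subsystem="Product"),
        _rxn("EX_bio", {"bio[e]": -1.0}, exchange=True, subsystem="Exchange"),
        _rxn("EX_prod", {"prod[e]": -1.0}, exchange=True, subsystem="Exchange"),
    ]
    return MetabolicModel(
        id="branched_toy", metabolites=mets, reactions=rxns,
        genes={"gT1", "gT2", "gB", "gP"}, objective_id="BIOMASS",
    )


# ---------------------------------------------------------------------------
# mini acarbose-producer model
# ---------------------------------------------------------------------------

#: single-copy product-pathway genes (the acb-cluster analogue): deleting
#: any one abolishes product formation but not growth
MINI_ACB_PRODUCT_GENES = (
    "acbC", "acbM", "acbA", "acbV", "acbS", "acbI", "acbJ", "acbW", "acbX",
)
MINI_ACB_TREY_GENE = "treY"

_MINI_METS: Tuple[Tuple[str, str, str], ...] = (
    # id, name, formula (simplified elemental bookkeeping)
    ("malt[e]", "maltose (ext)", "C12H24O12"),
    ("malt[c]", "maltose", "C12H24O12"),
    ("g6p[c]", "glucose 6-phosphate", "C6H12O6P"),
    ("g1p[c]", "glucose 1-phosphate", "C6H12O6P"),
    ("ru5p[c]", "pentose 5-phosphate pool", "C5H8O4P"),
    ("s7p[c]", "sedoheptulose 7-phosphate", "C7H10O5P"),
    ("gap[c]", "triose phosphate", "C3H6O3P"),
    ("pyr[c]", "pyruvate", "C3H4O3"),
    ("akg[c]", "2-oxoglutarate", "C5H6O4"),
    ("glu[c]", "L-glutamate", "C5H9O3N"),
    ("glu[e]", "L-glutamate (ext)", "C5H9O3N"),
    ("nh3[c]", "ammonia", "NH3"),
    ("nh3[e]", "ammonia (ext)", "NH3"),
    ("o2[c]", "oxygen", "O2"),
    ("o2[e]", "oxygen (ext)", "O2"),
    ("co2[c]", "carbon dioxide", "CO2"),
    ("co2[e]", "carbon dioxide (ext)", "CO2"),
    ("h2o[c]", "water", "H2O"),
    ("h2o[e]", "water (ext)", "H2O"),
    ("pi[e]", "phosphate (ext)", "POH2"),
    ("atp[c]", "ATP", "AP3"),
    ("adp[c]", "ADP", "AP2"),
    ("pi[c]", "phosphate", "POH2"),
    ("nad[c]", "NAD+", "D"),
    ("nadh[c]", "NADH", "DH2"),
    ("nadp[c]", "NADP+", "Q"),
    ("nadph[c]", "NADPH", "QH2"),
    ("tdp[c]", "dTDP carrier", "T"),
    ("tdpglc[c]", "dTDP-glucose", "C6H10O5T"),
    ("tdp4k[c]", "dTDP-4-keto-6-deoxyglucose", "C6H8O4T"),
    ("tdpam[c]", "dTDP-4-amino-4,6-dideoxyglucose", "C6H11O3NT"),
    ("cyc[c]", "C7-cyclitol", "C7H8O4"),
    ("cycp[c]", "C7-cyclitol 7-phosphate", "C7H8O4P"),
    ("acv7p[c]", "dTDP-acarviose 7-phosphate precursor", "C13H19O7NP"),
    ("acb7p[c]", "acarbose 7-phosphate", "C19H29O12NP"),
    ("acb[c]", "acarbose", "C19H27O11N"),
    ("acb[e]", "acarbose (ext)", "C19H27O11N"),
    ("compc[c]", "component C", "C19H27O11N"),
    ("compc[e]", "component C (ext)", "C19H27O11N"),
)

_GLY = "Glycolysis"
_PPP = "Pentose phosphate pathway"
_TCA = "TCA cycle and respiration"
_AA = "Amino acid metabolism"
_ACB = "Acarbose biosynthesis"
_TRANS = "Transport"
_EXCH = "Exchange"


def make_mini_acb() -> MetabolicModel:
    """The miniature acarbose-producer model (fixed construction).

    Biomass consumes glutamate, pyruvate, hexose phosphate, NADPH and ATP;
    the product pathway condenses a PPP-derived C7-cyclitol phosphate with
    a glutamate-aminated dTDP-sugar, glucosylates and dephosphorylates the
    intermediate and exports it through an ATP-driven two-subunit
    transporter.  Respiration is the only NADH sink, which couples both
    growth and product formation to oxygen uptake.
    """
    mets = [_met(mid, name, formula) for mid, name, formula in _MINI_METS]
    rxns = [
        # exchanges (uptake opened by the medium)
        _rxn("EX_malt", {"malt[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_nh3", {"nh3[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_o2", {"o2[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_glu", {"glu[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_h2o", {"h2o[e]": -1.0}, lb=-1000.0, exchange=True,
             subsystem=_EXCH),
        _rxn("EX_co2", {"co2[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_pi", {"pi[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_acb", {"acb[e]": -1.0}, exchange=True, subsystem=_EXCH),
        _rxn("EX_compc", {"compc[e]": -1.0}, exchange=True, subsystem=_EXCH),
        # transport
        _rxn("MALTabc",
             {"malt[e]": -1.0, "atp[c]": -1.0, "h2o[c]": -1.0,
              "malt[c]": 1.0, "adp[c]": 1.0, "pi[c]": 1.0},
             gpr="mstA", subsystem=_TRANS, name="maltose ABC importer"),
        _rxn("NH3t", {"nh3[e]": -1.0, "nh3[c]": 1.0}, gpr="amt1",
             subsystem=_TRANS),
        _rxn("GLUt", {"glu[e]": -1.0, "glu[c]": 1.0}, gpr="gltP",
             subsystem=_TRANS),
        _rxn("O2t", {"o2[e]": -1.0, "o2[c]": 1.0}, subsystem=_TRANS),
        _rxn("PIt", {"pi[e]": -1.0, "pi[c]": 1.0}, lb=-1000.0,
             subsystem=_TRANS),
        _rxn("H2Ot", {"h2o[c]": -1.0, "h2o[e]": 1.0}, lb=-1000.0,
             subsystem=_TRANS),
        _rxn("CO2t", {"co2[c]": -1.0, "co2[e]": 1.0}, subsystem=_TRANS),
        # central carbon metabolism
        _rxn("MALTK",
             {"malt[c]": -1.0, "atp[c]": -2.0,
              "g6p[c]": 1.0, "g1p[c]": 1.0, "adp[c]": 2.0},
             gpr="mak1", subsystem=_GLY, name="maltose phosphorylation"),
        _rxn("PGM", {"g1p[c]": -1.0, "g6p[c]": 1.0}, lb=-1000.0, gpr="pgm1",
             subsystem=_GLY, name="phosphoglucomutase"),
        _rxn("GLYC",
             {"g6p[c]": -1.0, "adp[c]": -3.0, "pi[c]": -2.0, "nad[c]": -2.0,
              "pyr[c]": 2.0, "atp[c]": 3.0, "nadh[c]": 2.0, "h2o[c]": 2.0},
             gpr="gly1", subsystem=_GLY, name="glycolysis (lumped)"),
        _rxn("GAPD",
             {"gap[c]": -1.0, "adp[c]": -1.0, "nad[c]": -1.0,
              "pyr[c]": 1.0, "atp[c]": 1.0, "nadh[c]": 1.0},
             gpr="gly2", subsystem=_GLY, name="lower glycolysis"),
        _rxn("PPPOX",
             {"g6p[c]": -1.0, "nadp[c]": -2.0,
              "ru5p[c]": 1.0, "co2[c]": 1.0, "nadph[c]": 2.0},
             gpr="zwf1", subsystem=_PPP, name="oxidative PPP"),
        _rxn("PPPNOX",
             {"ru5p[c]": -2.0, "s7p[c]": 1.0, "gap[c]": 1.0},
             gpr="tkt1", subsystem=_PPP, name="transketolase (S7P-forming)"),
        _rxn("PPPREC",
             {"ru5p[c]": -3.0, "h2o[c]": -3.0, "g6p[c]": 2.0, "gap[c]": 1.0},
             gpr="tal1", subsystem=_PPP, name="non-oxidative PPP recycle"),
        _rxn("AKGS",
             {"pyr[c]": -2.0, "nad[c]": -1.0,
              "akg[c]": 1.0, "co2[c]": 1.0, "nadh[c]": 1.0},
             gpr="tca1", subsystem=_TCA, name="2-oxoglutarate synthesis"),
        _rxn("TCA",
             {"pyr[c]": -1.0, "h2o[c]": -3.0, "nad[c]": -5.0,
              "co2[c]": 3.0, "nadh[c]": 5.0},
             gpr="tca2", subsystem=_TCA, name="pyruvate oxidation (lumped)"),
        _rxn("RESP",
             {"nadh[c]": -1.0, "o2[c]": -0.5, "adp[c]": -2.0, "pi[c]": -2.0,
              "nad[c]": 1.0, "h2o[c]": 3.0, "atp[c]": 2.0},
             gpr="resp1", subsystem=_TCA, name="oxidative phosphorylation"),
        _rxn("ATPM", {"atp[c]": -1.0, "h2o[c]": -1.0,
                      "adp[c]": 1.0, "pi[c]": 1.0},
             subsystem=_TCA, name="ATP maintenance (non-growth-associated)"),
        _rxn("THD", {"nadph[c]": -1.0, "nad[c]": -1.0,
                     "nadp[c]": 1.0, "nadh[c]": 1.0},
             subsystem=_TCA, name="transhydrogenase"),
        _rxn("GDH",
             {"akg[c]": -1.0, "nh3[c]": -1.0, "nadph[c]": -1.0,
              "glu[c]": 1.0, "h2o[c]": 1.0, "nadp[c]": 1.0},
             gpr="gdh1", subsystem=_AA, name="glutamate dehydrogenase"),
        # product pathway: C7-cyclitol branch
        _rxn("ACBC", {"s7p[c]": -1.0, "cyc[c]": 1.0, "pi[c]": 1.0},
             gpr="acbC", subsystem=_ACB, name="2-epi-5-epi-valiolone synthase"),
        _rxn("ACBM", {"cyc[c]": -1.0, "atp[c]": -1.0,
                      "cycp[c]": 1.0, "adp[c]": 1.0},
             gpr="acbM", subsystem=_ACB, name="cyclitol kinase"),
        # product pathway: dTDP-aminosugar branch
        _rxn("ACBA", {"g1p[c]": -1.0, "tdp[c]": -1.0,
                      "tdpglc[c]": 1.0, "pi[c]": 1.0},
             gpr="acbA", subsystem=_ACB, name="nucleotidyltransferase"),
        _rxn("ACBB", {"tdpglc[c]": -1.0, "tdp4k[c]": 1.0, "h2o[c]": 1.0},
             gpr="acbB or rmlB", subsystem=_ACB,
             name="dTDP-glucose 4,6-dehydratase (isozymes)"),
        _rxn("ACBV", {"tdp4k[c]": -1.0, "glu[c]": -1.0,
                      "tdpam[c]": 1.0, "akg[c]": 1.0},
             gpr="acbV", subsystem=_ACB,
             name="glutamate-dependent aminotransferase"),
        # product pathway: condensation, maturation, export
        _rxn("ACBS", {"cycp[c]": -1.0, "tdpam[c]": -1.0,
                      "acv7p[c]": 1.0, "tdp[c]": 1.0},
             gpr="acbS", subsystem=_ACB, name="condensation (glycosyltransfer)"),
        _rxn("ACBI", {"acv7p[c]": -1.0, "g6p[c]": -1.0,
                      "acb7p[c]": 1.0, "pi[c]": 1.0},
             gpr="acbI", subsystem=_ACB, name="glucosyl extension"),
        _rxn("ACBJ", {"acb7p[c]": -1.0, "acb[c]": 1.0, "pi[c]": 1.0},
             gpr="acbJ", subsystem=_ACB, name="product phosphatase"),
        _rxn("ACBT",
             {"acb[c]": -1.0, "atp[c]": -1.0, "h2o[c]": -1.0,
              "acb[e]": 1.0, "adp[c]": 1.0, "pi[c]": 1.0},
             gpr="acbW and acbX", subsystem=_ACB,
             name="product ABC exporter (two-subunit complex)"),
        # byproduct branch
        _rxn("TREY", {"acb7p[c]": -1.0, "compc[c]": 1.0, "pi[c]": 1.0},
             gpr="treY", subsystem=_ACB, name="TreY-like byproduct formation"),
        _rxn("COMPCt", {"compc[c]": -1.0, "compc[e]": 1.0}, subsystem=_TRANS),
        # biomass (exempt from elemental balance by convention)
        _rxn("BIOMASS",
             {"glu[c]": -0.45, "pyr[c]": -0.70, "g6p[c]": -0.15,
              "nadph[c]": -0.40, "atp[c]": -22.0, "h2o[c]": -22.0,
              "adp[c]": 22.0, "pi[c]": 22.0, "nadp[c]": 0.40},
             subsystem="Biomass", name="biomass equation"),
    ]
    genes = {
        "mstA", "amt1", "gltP", "mak1", "pgm1", "gly1", "gly2", "zwf1",
        "tkt1", "tal1", "tca1", "tca2", "resp1", "gdh1",
        "acbC", "acbM", "acbA", "acbB", "rmlB", "acbV", "acbS", "acbI",
        "acbJ", "acbW", "acbX", "treY",
    }
    return MetabolicModel(
        id="mini_acb", metabolites=mets, reactions=rxns, genes=genes,
        objective_id="BIOMASS",
    )


def mini_acb_media() -> Dict[str, MediumSpec]:
    """The two study media of the mini model.

    ``synthesis`` is the product-formation minimal medium (maltose +
    ammonium + unlimited oxygen and water); ``rich`` additionally supplies
    glutamate, so amino-acid-supply genes lose their essentiality there
    while every rich-medium-essential gene stays essential on the
    synthesis medium.
    """
    synthesis = MediumSpec(
        name="synthesis",
        uptake={"EX_malt": 1.0, "EX_nh3": 10.0, "EX_o2": 1000.0,
                "EX_h2o": 1000.0, "EX_pi": 1000.0},
    )
    rich = synthesis.with_uptake(EX_glu=1.0)
    rich.name = "rich"
    return {"synthesis": synthesis, "rich": rich}
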