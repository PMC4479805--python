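"""Model, medium and result I/O.

The canonical interchange format is a tabular (TSV) reaction-list dialect,
because published reconstructions of this kind ship as spreadsheets: a
``[reactions]`` section with id, name, equation string, bounds, GPR and
subsystem, plus an optional ``[metabolites]`` section with formula, charge
and compartment.  Equations are written left-to-right with positive
coefficients, ``->`` for irreversible and ``<=>`` for reversible steps,
and compartment-suffixed metabolite tokens (``g6p[c]``, ``malt[e]``).

SBML Level 3 with the flux-bounds/GPR conventions of the ``fbc`` package
is supported through python-libsbml for interoperability with other
constraint-based tools.  Medium configurations are flat YAML/JSON maps.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import yaml

from .gpr import GPR
from .medium import MediumSpec
from .model import (
    DEFAULT_IRREVERSIBLE_BOUNDS,
    DEFAULT_REVERSIBLE_BOUNDS,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
)

__all__ = [
    "ModelFormatError",
    "parse_formula",
    "format_formula",
    "parse_equation",
    "format_equation",
    "read_tabular_model",
    "write_tabular_model",
    "read_sbml",
    "write_sbml",
    "read_medium_config",
    "write_medium_config",
    "write_flux_table",
    "read_flux_table",
    "read_model",
    "write_model",
]

PathLike = Union[str, Path]


class ModelFormatError(ValueError):
    """Raised when a model/config file cannot be parsed."""


# ---------------------------------------------------------------------------
# formulas and equations
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?|)")


def parse_formula(text: str) -> Dict[str, float]:
    """Parse a Hill-style formula string (``C6H12O6``) into element counts."""
    if not text:
        return {}
    counts: Dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        element, num = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
        pos = m.end()
    if pos != len(text):
        raise ModelFormatError(f"cannot parse formula {text!r}")
    return counts


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def format_formula(counts: Mapping[str, float]) -> str:
    """Inverse of :func:`parse_formula` (elements in sorted order)."""
    parts = []
    for element in sorted(counts):
        n = counts[element]
        parts.append(element + ("" if n == 1 else _fmt_num(n)))
    return "".join(parts)


_MET_TOKEN = re.compile(r"^(.+\[[ce]\])$")
_COEFF_TOKEN = re.compile(r"^\d+(?:\.\d+)?(?:[eE][+-]?\d+)?$")


def _parse_side(text: str, sign: float, stoich: Dict[str, float]) -> None:
    text = text.strip()
    if not text:
        return
    for term in re.split(r"\s+\+\s+", text):
        tokens = term.strip().split(None, 1)
        if len(tokens) == 2 and _COEFF_TOKEN.match(tokens[0]):
            coeff, met = float(tokens[0]), tokens[1].strip()
        else:
            coeff, met = 1.0, term.strip()
        if not _MET_TOKEN.match(met):
            raise ModelFormatError(
                f"bad metabolite token {met!r} (expected id with [c]/[e] suffix)"
            )
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_equation(text: str) -> Tuple[Dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible)."""
    if "<=>" in text:
        left, right = text.split("<=>", 1)
        reversible = True
    elif "->" in text:
        left, right = text.split("->", 1)
        reversible = False
    else:
        raise ModelFormatError(f"equation {text!r} has no '->' or '<=>' arrow")
    stoich: Dict[str, float] = {}
    _parse_side(left, -1.0, stoich)
    _parse_side(right, +1.0, stoich)
    if not stoich:
        raise ModelFormatError(f"equation {text!r} names no metabolites")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    """Inverse of :func:`parse_equation`; substrate/product order sorted."""
    lhs = [
        (mid, -c) for mid, c in sorted(rxn.stoichiometry.items()) if c < 0
    ]
    rhs = [(mid, c) for mid, c in sorted(rxn.stoichiometry.items()) if c > 0]

    def side(terms: List[Tuple[str, float]]) -> str:
        return " + ".join(
            (f"{_fmt_num(c)} {mid}" if c != 1 else mid) for mid, c in terms
        )

    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["id", "name", "formula", "charge", "compartment"]
_RXN_COLUMNS = [
    "id", "name", "equation", "lower_bound", "upper_bound", "gpr", "subsystem",
]


def _norm_header(cells: List[str]) -> List[str]:
    return [c.strip().lower().replace(" ", "_") for c in cells]


def write_tabular_model(model: MetabolicModel, path: PathLike) -> None:
    """Write the model in the tabular dialect (deterministic output)."""
    lines = [
        "# acarflux model v1",
        f"# id: {model.id}",
        f"# objective: {model.objective_id or ''}",
        f"# genes: {','.join(sorted(model.genes))}",
        f"# n_metabolites: {len(model.metabolites)}",
        f"# n_reactions: {len(model.reactions)}",
        "[metabolites]",
        "\t".join(_MET_COLUMNS),
    ]
    for met in model.metabolites:
        lines.append("\t".join([
            met.id, met.name, format_formula(met.formula),
            "" if met.charge is None else str(met.charge), met.compartment,
        ]))
    lines.append("[reactions]")
    lines.append("\t".join(_RXN_COLUMNS))
    for rxn in model.reactions:
        lines.append("\t".join([
            rxn.id, rxn.name, format_equation(rxn),
            repr(rxn.lower_bound), repr(rxn.upper_bound),
            rxn.gpr.to_string(), rxn.subsystem,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tabular_model(path: PathLike) -> MetabolicModel:
    """Read a model from the tabular dialect.

    Header variants (case, spaces) are tolerated; a missing metabolite
    section is allowed (metabolites are then inferred from the equations
    with unknown formula/charge).  Declared ``n_metabolites`` /
    ``n_reactions`` counts, when present, guard against truncated files.
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    sections: Dict[str, List[List[str]]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip().lower()] = value.strip()
            continue
        if line.startswith("[") and line.rstrip().endswith("]"):
            current = line.strip()[1:-1].strip().lower()
            sections[current] = []
            continue
        if current is None:
            raise ModelFormatError(
                f"{path.name}:{lineno}: data before any section header"
            )
        sections[current].append(line.split("\t"))

    def table(name: str, columns: List[str]) -> List[Dict[str, str]]:
        rows = sections.get(name)
        if not rows:
            return []
        header = _norm_header(rows[0])
        unknown = set(header) - set(columns)
        if unknown:
            raise ModelFormatError(
                f"{path.name}: unknown {name} columns {sorted(unknown)}"
            )
        out = []
        for cells in rows[1:]:
            cells = cells + [""] * (len(header) - len(cells))
            out.append(dict(zip(header, (c.strip() for c in cells))))
        return out

    met_rows = table("metabolites", _MET_COLUMNS)
    rxn_rows = table("reactions", _RXN_COLUMNS)
    if "reactions" not in sections:
        raise ModelFormatError(f"{path.name}: no [reactions] section")

    if "n_reactions" in meta and int(meta["n_reactions"]) != len(rxn_rows):
        raise ModelFormatError(
            f"{path.name}: declared {meta['n_reactions']} reactions but "
            f"parsed {len(rxn_rows)} (truncated file?)"
        )
    if met_rows and "n_metabolites" in meta and \
            int(meta["n_metabolites"]) != len(met_rows):
        raise ModelFormatError(
            f"{path.name}: declared {meta['n_metabolites']} metabolites but "
            f"parsed {len(met_rows)} (truncated file?)"
        )

    metabolites: List[Metabolite] = []
    seen_mets = set()
    for row in met_rows:
        if row["id"] in seen_mets:
            raise ModelFormatError(f"duplicate metabolite id {row['id']!r}")
        seen_mets.add(row["id"])
        compartment = row.get("compartment") or (
            row["id"][-2] if row["id"].endswith(("[c]", "[e]")) else "c"
        )
        metabolites.append(Metabolite(
            id=row["id"], name=row.get("name", ""),
            formula=parse_formula(row.get("formula", "")),
            charge=int(row["charge"]) if row.get("charge") else None,
            compartment=compartment,
        ))

    reactions: List[Reaction] = []
    seen_rxns = set()
    for row in rxn_rows:
        rxn_id = row["id"]
        if rxn_id in seen_rxns:
            raise ModelFormatError(f"duplicate reaction id {rxn_id!r}")
        seen_rxns.add(rxn_id)
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ModelFormatError as exc:
            raise ModelFormatError(f"reaction {rxn_id!r}: {exc}") from exc
        defaults = (
            DEFAULT_REVERSIBLE_BOUNDS if reversible
            else DEFAULT_IRREVERSIBLE_BOUNDS
        )
        lb = float(row["lower_bound"]) if row.get("lower_bound") else defaults[0]
        ub = float(row["upper_bound"]) if row.get("upper_bound") else defaults[1]
        for met_id in stoich:
            if met_id not in seen_mets:
                seen_mets.add(met_id)
                metabolites.append(Metabolite(
                    id=met_id, name=met_id[:-3], compartment=met_id[-2],
                ))
        is_exchange = (
            len(stoich) == 1
            and next(iter(stoich)).endswith("[e]")
        )
        reactions.append(Reaction(
            id=rxn_id, name=row.get("name", ""), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub,
            gpr=GPR.parse(row.get("gpr", "")),
            subsystem=row.get("subsystem", ""), is_exchange=is_exchange,
        ))

    genes = (
        set(g for g in meta.get("genes", "").split(",") if g)
        if "genes" in meta
        else set().union(*(r.gpr.genes for r in reactions), set())
    )
    try:
        return MetabolicModel(
            id=meta.get("id", path.stem),
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_id=meta.get("objective") or None,
        )
    except ModelStructureError as exc:
        raise ModelFormatError(f"{path.name}: {exc}") from exc


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------

def _sbml_id(prefix: str, raw: str) -> str:
    return prefix + re.sub(r"[^A-Za-z0-9_]", "_", raw)


def _met_sbml_id(met: Metabolite) -> str:
    return _sbml_id("M_", met.id[:-3]) + f"_{met.compartment}"


def write_sbml(model: MetabolicModel, path: PathLike) -> None:
    """Write SBML L3V1 with fbc v2 bounds, gene products and objective.

    The subsystem label travels in the reaction notes.  Metabolite ids of
    the form ``base[c]`` map to species ids ``M_base_c`` and back.
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_id("", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in ("c", "e"):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    met_ids: Dict[str, str] = {}
    for met in model.metabolites:
        sid = _met_sbml_id(met)
        met_ids[met.id] = sid
        sp = sbml_model.createSpecies()
        sp.setId(sid)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)
        splug = sp.getPlugin("fbc")
        if met.formula and all(float(v).is_integer() for v in met.formula.values()):
            splug.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_id("G_", gene))
        gp.setLabel(gene)

    def bound_param(value: float, tag: str) -> str:
        pid = _sbml_id("", tag)
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        return pid

    def assoc_from_node(parent, node) -> None:
        if isinstance(node, str):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(_sbml_id("G_", node))
            return
        op, children = node
        group = parent.createAnd() if op == "and" else parent.createOr()
        for child in children:
            assoc_from_node(group, child)

    for rxn in model.reactions:
        rid = _sbml_id("R_", rxn.id)
        sr = sbml_model.createReaction()
        sr.setId(rid)
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        if rxn.subsystem:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_ids[met_id])
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound, f"{rid}_lb"))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound, f"{rid}_ub"))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            assoc_from_node(gpa, rxn.gpr.tree)

    if model.objective_id is not None:
        objective = mplug.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(_sbml_id("R_", model.objective_id))
        flux_obj.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _assoc_to_node(assoc):
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        label = assoc.getGeneProduct()
        return label[2:] if label.startswith("G_") else label
    if isinstance(assoc, (libsbml.FbcAnd, libsbml.FbcOr)):
        op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
        children = tuple(
            _assoc_to_node(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        if len(children) == 1:
            return children[0]
        return (op, children)
    raise ModelFormatError(f"unsupported GPR association {assoc}")


def read_sbml(path: PathLike) -> MetabolicModel:
    """Read an SBML L3 (fbc) constraint-based model.

    Reactions without fbc flux bounds get the conventional defaults with
    a warning.  Gene labels are preferred over gene-product ids.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelFormatError(
            f"SBML parse errors in {path}: "
            f"{doc.getErrorLog().toString()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: no model element")
    mplug = sbml_model.getPlugin("fbc")

    met_ids: Dict[str, str] = {}
    metabolites: List[Metabolite] = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sid = sp.getId()
        comp = sp.getCompartment()
        base = sid[2:] if sid.startswith("M_") else sid
        if base.endswith(f"_{comp}"):
            base = base[: -(len(comp) + 1)]
        met_id = f"{base}[{comp}]"
        met_ids[sid] = met_id
        splug = sp.getPlugin("fbc")
        formula = ""
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        metabolites.append(Metabolite(
            id=met_id, name=sp.getName() or base,
            formula=parse_formula(formula), charge=charge, compartment=comp,
        ))

    gene_labels: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def gpr_from_plugin(rplug) -> GPR:
        if rplug is None or rplug.getGeneProductAssociation() is None:
            return GPR.empty()
        node = _assoc_to_node(rplug.getGeneProductAssociation().getAssociation())

        def relabel(n):
            if isinstance(n, str):
                return gene_labels.get("G_" + n, gene_labels.get(n, n))
            op, children = n
            return (op, tuple(relabel(c) for c in children))

        node = relabel(node)
        return GPR.parse(_node_to_string(node))

    subsystem_re = re.compile(r"SUBSYSTEM:\s*([^<]*)")
    reactions: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rid = sr.getId()
        rxn_id = rid[2:] if rid.startswith("R_") else rid
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = met_ids[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = met_ids[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            for getter, which in (
                (rplug.getLowerFluxBound, "lb"),
                (rplug.getUpperFluxBound, "ub"),
            ):
                pid = getter()
                param = sbml_model.getParameter(pid) if pid else None
                if param is not None:
                    if which == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
        if lb is None or ub is None:
            defaults = (
                DEFAULT_REVERSIBLE_BOUNDS if sr.getReversible()
                else DEFAULT_IRREVERSIBLE_BOUNDS
            )
            warnings.warn(
                f"reaction {rxn_id!r}: missing flux bounds, applying "
                f"defaults {defaults}", stacklevel=2,
            )
            lb = defaults[0] if lb is None else lb
            ub = defaults[1] if ub is None else ub
        subsystem = ""
        if sr.isSetNotes():
            m = subsystem_re.search(sr.getNotesString())
            if m:
                subsystem = m.group(1).strip()
        is_exchange = (
            len(stoich) == 1 and next(iter(stoich)).endswith("[e]")
        )
        reactions.append(Reaction(
            id=rxn_id, name=sr.getName() or rxn_id, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr_from_plugin(rplug),
            subsystem=subsystem, is_exchange=is_exchange,
        ))

    objective_id = None
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            target = obj.getFluxObjective(0).getReaction()
            objective_id = target[2:] if target.startswith("R_") else target

    genes = set(gene_labels.values()) | set().union(
        *(r.gpr.genes for r in reactions), set()
    )
    return MetabolicModel(
        id=sbml_model.getId() or Path(path).stem,
        metabolites=metabolites, reactions=reactions,
        genes=genes, objective_id=objective_id,
    )


def _node_to_string(node) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    parts = []
    for child in children:
        text = _node_to_string(child)
        if not isinstance(child, str):
            text = f"({text})"
        parts.append(text)
    return f" {op} ".join(parts)


# ---------------------------------------------------------------------------
# medium configs and flux tables
# ---------------------------------------------------------------------------

def read_medium_config(path: PathLike) -> MediumSpec:
    """Read a medium from a flat YAML/JSON mapping.

    Either ``{name, uptake: {...}, fixed: {...}}`` or a bare
    ``{exchange_id: cap}`` map (treated as uptake caps).  Negative rates
    are rejected.
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ModelFormatError(f"{path}: medium config must be a mapping")
    if "uptake" in data or "fixed" in data or "name" in data:
        uptake = data.get("uptake") or {}
        fixed = data.get("fixed") or {}
        name = data.get("name") or Path(path).stem
    else:
        uptake, fixed, name = data, {}, Path(path).stem
    try:
        return MediumSpec(
            name=str(name),
            uptake={str(k): float(v) for k, v in uptake.items()},
            fixed={str(k): float(v) for k, v in fixed.items()},
        )
    except ValueError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc


def write_medium_config(medium: MediumSpec, path: PathLike) -> None:
    payload = {"name": medium.name, "uptake": dict(medium.uptake)}
    if medium.fixed:
        payload["fixed"] = dict(medium.fixed)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def write_flux_table(
    solution,
    path: PathLike,
    model: Optional[MetabolicModel] = None,
) -> None:
    """Write a solved flux vector as TSV (reaction id, flux, subsystem).

    Fluxes are printed at 6 significant digits; column order is fixed.
    """
    if not solution.ok:
        raise ValueError(
            f"cannot write flux table for a solution with status "
            f"{solution.status!r}"
        )
    subsystems = (
        {r.id: r.subsystem for r in model.reactions} if model is not None else {}
    )
    lines = ["reaction_id\tflux\tsubsystem"]
    for rxn_id in solution.fluxes:
        lines.append(
            f"{rxn_id}\t{solution.fluxes[rxn_id]:.6g}\t"
            f"{subsystems.get(rxn_id, '')}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_flux_table(path: PathLike) -> Dict[str, float]:
    lines = Path(path).read_text().splitlines()
    if not lines or _norm_header(lines[0].split("\t"))[:2] != ["reaction_id", "flux"]:
        raise ModelFormatError(f"{path}: not a flux table")
    out: Dict[str, float] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        out[cells[0]] = float(cells[1])
    return out


# ---------------------------------------------------------------------------
# dispatch by extension
# ---------------------------------------------------------------------------

def read_model(path: PathLike) -> MetabolicModel:
    """Read a model, dispatching on the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return read_sbml(path)
    return read_tabular_model(path)


def write_model(model: MetabolicModel, path: PathLike) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        write_sbml(model, path)
    else:
        write_tabular_model(model, path)
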