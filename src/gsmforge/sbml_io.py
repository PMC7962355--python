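"""SBML Level 3 Version 1 + FBC v2 input/output.

Flux bounds and gene associations travel through the FBC constructs; the
growth objective is the FBC active objective.  Reaction roles (exchange,
demand, biomass, ATP maintenance) are encoded as the community-standard
SBO terms on write and recovered from them on read, falling back to id
patterns for files that lack SBO annotation.  Output element ordering is
sorted by id, so writing the same model twice yields byte-identical files.
"""

from __future__ import annotations

import libsbml

from gsmforge.gpr import GprExpression
from gsmforge.model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ReactionKind,
    infer_reaction_kind,
)


class SbmlReadError(ValueError):
    """Malformed, non-SBML or non-FBC input."""


_SBO_BY_KIND = {
    ReactionKind.EXCHANGE: 627,
    ReactionKind.DEMAND: 628,
    ReactionKind.BIOMASS: 629,
    ReactionKind.MAINTENANCE: 630,
}
_KIND_BY_SBO = {v: k for k, v in _SBO_BY_KIND.items()}


# ---------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------

def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML L3 FBC-v2 file into a :class:`MetabolicModel`.

    Raises :class:`SbmlReadError` for malformed XML (naming the line),
    missing FBC package, or dangling metabolite/gene references, and
    :class:`ModelValidationError` if the parsed content violates model
    invariants.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise SbmlReadError(
            f"SBML parse error at line {first.getLine()}: {first.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SbmlReadError("document contains no model")
    mplug = sbml_model.getPlugin("fbc")
    if mplug is None:
        raise SbmlReadError(
            "unsupported dialect: SBML document lacks the FBC package "
            "(flux bounds and gene associations are required)"
        )

    compartments = {
        c.getId(): c.getName() or c.getId()
        for c in (sbml_model.getCompartment(i) for i in range(sbml_model.getNumCompartments()))
    }

    metabolites: dict[str, Metabolite] = {}
    boundary: set[str] = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = ""
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue  # boundary species are not balanced; drop from network
        metabolites[sp.getId()] = Metabolite(
            id=sp.getId(),
            compartment=sp.getCompartment(),
            name=sp.getName(),
            formula=formula,
            charge=charge,
        )

    gene_products = {
        mplug.getGeneProduct(i).getId()
        for i in range(mplug.getNumGeneProducts())
    }

    objective_id = ""
    active = mplug.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective_id = active.getFluxObjective(0).getReaction()

    reactions: dict[str, Reaction] = {}
    genes: set[str] = set()
    dangling_mets: set[str] = set()
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        touches_boundary = False
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            sid = ref.getSpecies()
            if sid in boundary:
                touches_boundary = True
                continue
            if sid not in metabolites:
                dangling_mets.add(sid)
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            sid = ref.getSpecies()
            if sid in boundary:
                touches_boundary = True
                continue
            if sid not in metabolites:
                dangling_mets.add(sid)
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()

        rplug = rxn.getPlugin("fbc")
        if rplug is None:
            raise SbmlReadError(f"reaction {rxn.getId()!r} lacks FBC bounds")
        lb = _bound_value(sbml_model, rplug.getLowerFluxBound(), -DEFAULT_BOUND)
        ub = _bound_value(sbml_model, rplug.getUpperFluxBound(), DEFAULT_BOUND)

        gpr = GprExpression.empty()
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None and gpa.getAssociation() is not None:
            gpr = _association_to_gpr(gpa.getAssociation(), gene_products)
        genes |= gpr.genes()

        kind = _KIND_BY_SBO.get(rxn.getSBOTerm())
        if kind is None:
            kind = infer_reaction_kind(
                rxn.getId(),
                len(stoich),
                touches_boundary=touches_boundary,
                biomass_ids={objective_id} if objective_id else None,
            )
        reactions[rxn.getId()] = Reaction(
            id=rxn.getId(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            kind=kind,
            name=rxn.getName(),
        )

    if dangling_mets:
        raise SbmlReadError(
            f"reactions reference undeclared species: {sorted(dangling_mets)}"
        )
    if not objective_id or objective_id not in reactions:
        raise SbmlReadError("no usable FBC active objective found")

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        compartments=compartments,
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction=objective_id,
    )
    model.validate()
    return model


def _bound_value(sbml_model, param_id: str, default: float) -> float:
    if not param_id:
        return default
    param = sbml_model.getParameter(param_id)
    if param is None:
        raise SbmlReadError(f"flux bound references unknown parameter {param_id!r}")
    return param.getValue()


def _association_to_gpr(assoc, declared: set[str]) -> GprExpression:
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        if gid not in declared:
            raise SbmlReadError(
                f"GPR references undeclared gene product: [{gid!r}]"
            )
        return GprExpression.leaf(gid)
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i), declared)
        for i in range(assoc.getNumAssociations())
    )
    if assoc.isFbcAnd():
        return GprExpression("and", children=children).simplify()
    if assoc.isFbcOr():
        return GprExpression("or", children=children).simplify()
    raise SbmlReadError("unsupported GPR association node")


# ---------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML L3V1 + FBC v2 with sorted, deterministic
    element ordering."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setName(model.compartments[cid])
        comp.setConstant(True)
        comp.setSize(1.0)

    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        sp = sm.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula:
            splug.setChemicalFormula(met.formula)

    for gid in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(gid)

    # one shared parameter per distinct bound value
    bound_values = sorted(
        {r.lower_bound for r in model.reactions.values()}
        | {r.upper_bound for r in model.reactions.values()}
    )
    bound_param: dict[float, str] = {}
    for k, value in enumerate(bound_values):
        pid = f"fb_{k}"
        param = sm.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        bound_param[value] = pid

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sr = sm.createReaction()
        sr.setId(rxn.id)
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        if rxn.kind in _SBO_BY_KIND:
            sr.setSBOTerm(_SBO_BY_KIND[rxn.kind])
        for mid in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[mid]
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(mid)
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param[rxn.lower_bound])
        rplug.setUpperFluxBound(bound_param[rxn.upper_bound])
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, gpa)

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(model.objective_reaction)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path!r}")


def _gpr_to_association(gpr: GprExpression, parent) -> None:
    """Recursively build libsbml FbcAssociation nodes mirroring the tree."""
    if gpr.op == "leaf":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gpr.gene)
        return
    if gpr.op == "and":
        node = parent.createAnd()
    elif gpr.op == "or":
        node = parent.createOr()
    else:  # pragma: no cover - empty handled by caller
        raise ModelValidationError("cannot serialize the empty GPR")
    for child in gpr.children:
        _gpr_to_association(child, node)
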