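"""In-memory representation of a constraint-based metabolic model.

The model is a compartmentalized stoichiometric network: metabolites with
elemental formula and charge, reactions with rational stoichiometry, flux
bounds (mmol/gDW/h) and a boolean GPR, plus a designated objective
(biomass) reaction whose optimal flux is the specific growth rate µ in
1/h.  Also provided: elemental/charge balance auditing and compartment-wise
comparison of two models sharing a reaction id namespace.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from gsmforge.formula import FormulaError, parse_formula
from gsmforge.gpr import GprExpression

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A structural invariant of the model is violated."""


class ReactionKind(str, enum.Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"
    DEMAND = "demand"

    @property
    def is_boundary_or_pseudo(self) -> bool:
        """Kinds exempt from mass/charge balance (boundary or pseudo-reactions)."""
        return self is not ReactionKind.INTERNAL


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` uses the narrow Hill-style grammar of
    :mod:`gsmforge.formula`; an empty string flags the metabolite as
    unannotated.  ``charge`` is the signed formal charge.
    """

    id: str
    compartment: str
    name: str = ""
    formula: str = ""
    charge: int = 0

    def element_counts(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds and gene association.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative =
    consumed).  Bounds are in mmol/gDW/h.  ``kind`` distinguishes internal
    chemistry from boundary/pseudo-reactions: exchanges import/export a
    single species, the biomass pseudo-reaction drains precursors (its flux
    is µ), and the maintenance reaction carries the fixed NGAM ATP cost as
    its lower bound.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression = field(default_factory=GprExpression.empty)
    kind: ReactionKind = ReactionKind.INTERNAL
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"> upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A compartmentalized stoichiometric network with one growth objective."""

    id: str
    compartments: dict[str, str]  # id -> display name
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    genes: set[str]
    objective_reaction: str

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            genes=set(self.genes),
            objective_reaction=self.objective_reaction,
        )

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise ModelValidationError on the
        first violation, listing the offending ids."""
        for met in self.metabolites.values():
            if not met.id:
                raise ModelValidationError("metabolite with empty id")
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r} references unknown compartment "
                    f"{met.compartment!r}"
                )
        for rxn in self.reactions.values():
            missing = sorted(m for m in rxn.stoichiometry if m not in self.metabolites)
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites: {missing}"
                )
            if rxn.kind is ReactionKind.INTERNAL and not rxn.stoichiometry:
                raise ModelValidationError(
                    f"internal reaction {rxn.id!r} has empty stoichiometry"
                )
            if rxn.kind is ReactionKind.EXCHANGE and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one "
                    f"metabolite, found {len(rxn.stoichiometry)}"
                )
            unknown_genes = sorted(rxn.gpr.genes() - self.genes)
            if unknown_genes:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR references undeclared genes: "
                    f"{unknown_genes}"
                )
        if self.objective_reaction not in self.reactions:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # -- convenience --------------------------------------------------

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind is ReactionKind.EXCHANGE]

    def reaction_compartments(self, rxn_id: str) -> frozenset[str]:
        """Compartments hosting at least one participant of the reaction.
        Transport reactions therefore belong to ≥2 compartments."""
        rxn = self.reactions[rxn_id]
        return frozenset(
            self.metabolites[m].compartment for m in rxn.stoichiometry
        )


# -- reaction kind inference (SBML carries no explicit roles) ----------

def infer_reaction_kind(
    rxn_id: str,
    n_metabolites: int,
    touches_boundary: bool = False,
    biomass_ids: set[str] | None = None,
    maintenance_ids: set[str] | None = None,
) -> ReactionKind:
    """Heuristic role assignment used when reading interchange files.

    Explicit ``biomass_ids``/``maintenance_ids`` win; otherwise ids are
    pattern-matched (``EX_``/``DM_`` prefixes, ``biomass``/``atpm``
    substrings), and single-metabolite boundary reactions count as
    exchanges.
    """
    if biomass_ids and rxn_id in biomass_ids:
        return ReactionKind.BIOMASS
    if maintenance_ids and rxn_id in maintenance_ids:
        return ReactionKind.MAINTENANCE
    low = rxn_id.lower()
    if rxn_id.startswith("EX_") or (n_metabolites == 1 and touches_boundary):
        return ReactionKind.EXCHANGE
    if rxn_id.startswith("DM_"):
        return ReactionKind.DEMAND
    if "biomass" in low:
        return ReactionKind.BIOMASS
    if low in ("atpm", "ngam") or "maintenance" in low:
        return ReactionKind.MAINTENANCE
    return ReactionKind.INTERNAL


# -- balance checking --------------------------------------------------

BALANCED = "balanced"
MASS_UNBALANCED = "mass-unbalanced"
CHARGE_UNBALANCED = "charge-unbalanced"
BOTH_UNBALANCED = "both"
EXEMPT = "exempt"
UNKNOWN_FORMULA = "unknown-formula"

_BALANCE_TOL = 1e-6


@dataclass
class BalanceReport:
    """Per-reaction mass/charge balance audit.

    ``fraction_balanced`` is taken over reactions that are neither exempt
    (exchange/biomass/demand/maintenance pseudo-reactions) nor of unknown
    formula, mirroring how published reconstructions report balance
    percentages over the auditable reaction set.
    """

    status: dict[str, str]
    formula_errors: dict[str, list[str]]  # reaction id -> messages

    @property
    def fraction_balanced(self) -> float:
        audited = [
            s for s in self.status.values() if s not in (EXEMPT, UNKNOWN_FORMULA)
        ]
        if not audited:
            return 1.0
        return sum(s == BALANCED for s in audited) / len(audited)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.status.values():
            out[s] = out.get(s, 0) + 1
        return out

    def to_rows(self) -> list[dict[str, str]]:
        return [
            {"reaction": rid, "status": status}
            for rid, status in sorted(self.status.items())
        ]


def check_balance(model: MetabolicModel) -> BalanceReport:
    """Audit elemental and charge balance of every reaction.

    For each non-exempt reaction, mass balance requires
    Σ coefficient × element-count = 0 for every element, and charge balance
    Σ coefficient × charge = 0.  A reaction with any formula-less or
    unparsable participant is reported ``unknown-formula`` rather than
    guessed at.
    """
    status: dict[str, str] = {}
    errors: dict[str, list[str]] = {}
    for rxn in model.reactions.values():
        if rxn.kind.is_boundary_or_pseudo:
            status[rxn.id] = EXEMPT
            continue
        element_sum: dict[str, float] = {}
        charge_sum = 0.0
        unknown = False
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if not met.formula:
                unknown = True
                continue
            try:
                counts = met.element_counts()
            except FormulaError as exc:
                unknown = True
                errors.setdefault(rxn.id, []).append(str(exc))
                continue
            for el, n in counts.items():
                element_sum[el] = element_sum.get(el, 0.0) + coeff * n
            charge_sum += coeff * met.charge
        if unknown:
            status[rxn.id] = UNKNOWN_FORMULA
            continue
        mass_ok = all(abs(v) <= _BALANCE_TOL for v in element_sum.values())
        charge_ok = abs(charge_sum) <= _BALANCE_TOL
        if mass_ok and charge_ok:
            status[rxn.id] = BALANCED
        elif not mass_ok and not charge_ok:
            status[rxn.id] = BOTH_UNBALANCED
        elif not mass_ok:
            status[rxn.id] = MASS_UNBALANCED
        else:
            status[rxn.id] = CHARGE_UNBALANCED
    return BalanceReport(status=status, formula_errors=errors)


# -- model comparison --------------------------------------------------

@dataclass
class ModelComparison:
    """Compartment-wise reaction-set overlap and global feature counts.

    A reaction is counted in every compartment hosting at least one of its
    participants, so transport reactions appear in each compartment they
    bridge.
    """

    per_compartment: dict[str, tuple[int, int, int]]  # shared, only_a, only_b
    counts_a: dict[str, int]
    counts_b: dict[str, int]

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {
                "compartment": comp,
                "shared": shared,
                "unique_to_a": only_a,
                "unique_to_b": only_b,
            }
            for comp, (shared, only_a, only_b) in sorted(self.per_compartment.items())
        ]


def _feature_counts(model: MetabolicModel) -> dict[str, int]:
    return {
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
    }


def compare_models(a: MetabolicModel, b: MetabolicModel) -> ModelComparison:
    """Compare two models sharing a reaction id namespace."""
    comps = sorted(set(a.compartments) | set(b.compartments))
    per_comp: dict[str, tuple[int, int, int]] = {}
    for comp in comps:
        in_a = {r for r in a.reactions if comp in a.reaction_compartments(r)}
        in_b = {r for r in b.reactions if comp in b.reaction_compartments(r)}
        per_comp[comp] = (
            len(in_a & in_b),
            len(in_a - in_b),
            len(in_b - in_a),
        )
    return ModelComparison(
        per_compartment=per_comp,
        counts_a=_feature_counts(a),
        counts_b=_feature_counts(b),
    )


# -- model editing -----------------------------------------------------

def add_reaction(
    model: MetabolicModel,
    reaction: Reaction,
    new_metabolites: list[Metabolite] = (),
    new_genes: set[str] | list[str] = (),
) -> MetabolicModel:
    """Return a copy of ``model`` with ``reaction`` (plus any new
    metabolites and genes) inserted and all invariants re-validated."""
    if reaction.id in model.reactions:
        raise ModelValidationError(f"reaction id {reaction.id!r} already present")
    out = model.copy()
    for met in new_metabolites:
        if met.id in out.metabolites and out.metabolites[met.id] != met:
            raise ModelValidationError(
                f"metabolite {met.id!r} already present with different attributes"
            )
        out.metabolites[met.id] = met
    out.genes.update(new_genes)
    out.reactions[reaction.id] = reaction
    out.validate()
    return out


def remove_reaction(model: MetabolicModel, rxn_id: str) -> MetabolicModel:
    """Return a copy without ``rxn_id``; orphaned metabolites/genes are kept
    (pruning is a separate, explicit decision)."""
    if rxn_id not in model.reactions:
        raise ModelValidationError(f"reaction {rxn_id!r} not in model")
    if rxn_id == model.objective_reaction:
        raise ModelValidationError("cannot remove the objective reaction")
    out = model.copy()
    del out.reactions[rxn_id]
    return out


def set_bounds(
    model: MetabolicModel, rxn_id: str, lower: float, upper: float
) -> MetabolicModel:
    """Return a copy with the bounds of one reaction replaced."""
    if rxn_id not in model.reactions:
        raise ModelValidationError(f"reaction {rxn_id!r} not in model")
    out = model.copy()
    out.reactions[rxn_id] = replace(
        out.reactions[rxn_id], lower_bound=lower, upper_bound=upper
    )
    return out
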