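"""Linear-programming core: flux balance analysis and friends.

FBA solves ``max c·v  s.t.  S·v = 0,  lb ≤ v ≤ ub`` where S is the
stoichiometric matrix; the flux of the biomass pseudo-reaction at the
optimum is the specific growth rate µ (1/h).  Also here: parsimonious
refinement (minimum total |v| at fixed optimal objective), flux
variability analysis, blocked-reaction detection, medium construction and
per-substrate growth simulation.

The LP itself is delegated to scipy's HiGHS interface; everything above it
(problem construction, media semantics, growth calls) is owned by this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from gsmforge.model import MetabolicModel, ReactionKind

#: numerical tolerances (LP noise floor on bounds of order 1000)
FEASIBILITY_TOL = 1e-9
BLOCKED_TOL = 1e-9
#: µ above this value counts as growth
GROWTH_THRESHOLD = 1e-6
#: community-convention single-substrate uptake rate, mmol/gDW/h
DEFAULT_UPTAKE = 10.0

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class FbaError(RuntimeError):
    """Raised for structural problems (unknown ids, infeasible base FVA)."""


@dataclass
class FluxResult:
    """Outcome of one LP solve."""

    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class MediumSpec:
    """A single-carbon-source growth medium.

    ``carbon_source`` is the exchange reaction id of the sole carbon
    source, opened for uptake at ``uptake_rate``.  ``free_exchanges`` are
    open in both directions (water, protons); ``uptake_exchanges`` are the
    inorganic nutrients opened for uptake (O2, NH4+, phosphate, sulfate).
    Every other exchange is secretion-only, so overflow metabolism stays
    possible while no alternative carbon enters.
    """

    carbon_source: str
    uptake_rate: float = DEFAULT_UPTAKE
    free_exchanges: frozenset[str] = frozenset()
    uptake_exchanges: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.uptake_rate <= 0:
            raise ValueError("uptake_rate must be positive")


@dataclass
class GrowthCallSet:
    """Binary metabolized/not-metabolized calls per substrate.

    ``provenance`` is ``"simulated"`` (FBA) or ``"measured"`` (phenotype
    microarray); ``threshold`` records the growth cutoff used.  ``values``
    holds the underlying quantitative readout (µ for simulations, positive
    replicate fraction for measurements) and ``reasons`` any per-substrate
    notes (e.g. a substrate with no exchange reaction).
    """

    calls: dict[str, bool]
    provenance: str
    threshold: float
    values: dict[str, float] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {
                "substrate": s,
                "call": "growth" if g else "no-growth",
                "value": self.values.get(s, float("nan")),
                "reason": self.reasons.get(s, ""),
            }
            for s, g in sorted(self.calls.items())
        ]


# ---------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------

def _problem(model: MetabolicModel):
    """Stoichiometric matrix and bounds in a fixed reaction/metabolite order."""
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for mid, coeff in rxn.stoichiometry.items():
            S[met_index[mid], j] += coeff
    return rxn_ids, S, lb, ub


_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


def _solve(c, S, lb, ub, extra_ub=None, extra_b=None):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=extra_ub,
        b_ub=extra_b,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:  # numerical failure - surface it
        raise FbaError(f"LP solver failure: {res.message}")
    return status, res


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------

def fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
) -> FluxResult:
    """Flux balance analysis.  ``objective`` defaults to the model's
    designated growth reaction.  Infeasible/unbounded problems are
    reported in the result status, never raised."""
    objective = objective or model.objective_reaction
    if objective not in model.reactions:
        raise FbaError(f"unknown objective reaction {objective!r}")
    if direction not in ("max", "min"):
        raise FbaError(f"direction must be 'max' or 'min', got {direction!r}")
    rxn_ids, S, lb, ub = _problem(model)
    c = np.zeros(len(rxn_ids))
    sign = -1.0 if direction == "max" else 1.0
    c[rxn_ids.index(objective)] = sign
    status, res = _solve(c, S, lb, ub)
    if status != OPTIMAL:
        return FluxResult(status=status, objective_value=float("nan"), fluxes={})
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxResult(status=OPTIMAL, objective_value=fluxes[objective], fluxes=fluxes)


def pfba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
) -> FluxResult:
    """Parsimonious FBA: among all optima of :func:`fba`, return the flux
    vector of minimum total |v|.  FBA optima are generically degenerate;
    the parsimonious refinement makes the returned vector reproducible and
    solver-independent up to remaining exact ties."""
    base = fba(model, objective, direction)
    if not base.ok:
        return base
    objective = objective or model.objective_reaction
    rxn_ids, S, lb, ub = _problem(model)
    n = len(rxn_ids)
    j = rxn_ids.index(objective)
    opt = base.objective_value
    # pin the objective to its optimum (tiny relaxation for LP round-off)
    slack = 1e-9 * max(1.0, abs(opt))
    lb2, ub2 = lb.copy(), ub.copy()
    if direction == "max":
        lb2[j] = max(lb2[j], opt - slack)
    else:
        ub2[j] = min(ub2[j], opt + slack)
    # min sum t, t >= v, t >= -v  (variables [v, t])
    S2 = np.hstack([S, np.zeros_like(S)])
    A_ub = np.vstack(
        [
            np.hstack([np.eye(n), -np.eye(n)]),
            np.hstack([-np.eye(n), -np.eye(n)]),
        ]
    )
    b_ub = np.zeros(2 * n)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    big = np.maximum(np.abs(lb2), np.abs(ub2))
    status, res = _solve(
        c,
        S2,
        np.concatenate([lb2, np.zeros(n)]),
        np.concatenate([ub2, big]),
        extra_ub=A_ub,
        extra_b=b_ub,
    )
    if status != OPTIMAL:
        # fall back on the raw optimum rather than failing the caller
        return base
    fluxes = dict(zip(rxn_ids, res.x[:n]))
    return FluxResult(status=OPTIMAL, objective_value=fluxes[objective], fluxes=fluxes)


def fva(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    objective_fraction: float = 0.0,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis: per-reaction (min, max) flux, optionally
    with the growth objective constrained to ≥ fraction × its optimum."""
    rxn_ids, S, lb, ub = _problem(model)
    targets = rxn_ids if reactions is None else list(reactions)
    unknown = sorted(set(targets) - set(rxn_ids))
    if unknown:
        raise FbaError(f"unknown reactions in FVA request: {unknown}")
    if objective_fraction > 0:
        base = fba(model)
        if not base.ok:
            raise FbaError(f"FVA base problem is {base.status}")
        j = rxn_ids.index(model.objective_reaction)
        lb = lb.copy()
        lb[j] = max(lb[j], objective_fraction * base.objective_value - FEASIBILITY_TOL)
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        lo_hi = []
        for sign in (1.0, -1.0):
            c[j] = sign
            status, res = _solve(c, S, lb, ub)
            if status != OPTIMAL:
                raise FbaError(f"FVA subproblem for {rid!r} is {status}")
            lo_hi.append(sign * res.fun)
        out[rid] = (lo_hi[0], lo_hi[1])
    return out


def blocked_reactions(model: MetabolicModel) -> set[str]:
    """Reactions unable to carry flux in any steady state with every
    exchange opened to ±1000 and no objective constraint.  Internal loops
    can carry flux and are therefore not blocked."""
    opened = model.copy()
    for rxn in list(opened.reactions.values()):
        if rxn.kind is ReactionKind.EXCHANGE:
            opened.reactions[rxn.id] = replace(
                rxn, lower_bound=-1000.0, upper_bound=1000.0
            )
        elif rxn.lower_bound > 0 or rxn.upper_bound < 0:
            # relax enforced fluxes (e.g. maintenance lower bounds) so the
            # structural probe admits v = 0 and can never be infeasible;
            # directionality is preserved
            opened.reactions[rxn.id] = replace(
                rxn,
                lower_bound=min(rxn.lower_bound, 0.0),
                upper_bound=max(rxn.upper_bound, 0.0),
            )
    ranges = fva(opened, objective_fraction=0.0)
    return {
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) <= BLOCKED_TOL and abs(hi) <= BLOCKED_TOL
    }


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set for the medium.

    The carbon source's exchange gets lower bound −uptake_rate; free and
    inorganic-uptake exchanges are opened — but a model-intrinsic uptake
    cap (an already-negative lower bound) is respected, the medium only
    grants availability; every other exchange becomes secretion-only
    (lower bound 0).  Idempotent."""
    exchange_ids = {r.id for r in model.exchanges()}
    for rid in {medium.carbon_source} | set(medium.free_exchanges) | set(
        medium.uptake_exchanges
    ):
        if rid not in exchange_ids:
            raise FbaError(f"medium references unknown exchange {rid!r}")
    out = model.copy()
    for rid in exchange_ids:
        rxn = out.reactions[rid]
        if rid == medium.carbon_source:
            lower = -medium.uptake_rate
        elif rid in medium.free_exchanges or rid in medium.uptake_exchanges:
            lower = rxn.lower_bound if rxn.lower_bound < 0 else -1000.0
        else:
            lower = 0.0
        out.reactions[rid] = replace(
            rxn, lower_bound=lower, upper_bound=max(rxn.upper_bound, 0.0)
        )
    return out


def simulate_substrate_growth(
    model: MetabolicModel,
    substrates: dict[str, str] | list[str],
    base_medium: MediumSpec,
    uptake_rate: float = DEFAULT_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> GrowthCallSet:
    """Simulate growth on each substrate as sole carbon source.

    ``substrates`` maps substrate name → exchange id (or is a list of
    exchange ids used as their own names).  A substrate whose exchange is
    absent from the model is called no-growth with a recorded reason —
    this is exactly the situation that drives adding new substrate
    pathways to a draft reconstruction."""
    if isinstance(substrates, list):
        substrates = {s: s for s in substrates}
    exchange_ids = {r.id for r in model.exchanges()}
    calls: dict[str, bool] = {}
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for name in substrates:
        ex = substrates[name]
        if ex not in exchange_ids:
            calls[name] = False
            values[name] = 0.0
            reasons[name] = f"no exchange reaction {ex!r} in model"
            continue
        medium = replace(base_medium, carbon_source=ex, uptake_rate=uptake_rate)
        result = fba(apply_medium(model, medium))
        mu = result.objective_value if result.ok else 0.0
        calls[name] = mu > growth_threshold
        values[name] = mu
        if not result.ok:
            reasons[name] = result.status
    return GrowthCallSet(
        calls=calls,
        provenance="simulated",
        threshold=growth_threshold,
        values=values,
        reasons=reasons,
    )
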