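"""FSEOF: flux scanning based on enforced objective flux.

A two-stage scan for overexpression candidates.  Stage one computes the
theoretical maximum product flux with biomass fixed to zero.  Stage two
enforces the product flux in steps (as a rising lower bound on the
product exchange, up to a fraction of the theoretical maximum), maximizes
biomass at each step, and refines each optimum parsimoniously so flux
vectors are reproducible despite degenerate optima.  Reactions whose flux
rises monotonically with the enforced product flux — without changing
direction — are amplification (overexpression) targets; reactions that
lose flux are competing pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from gsmforge.fba import FbaError, GROWTH_THRESHOLD, fba, pfba
from gsmforge.model import MetabolicModel, set_bounds

AMPLIFICATION_TARGET = "amplification-target"
NON_MONOTONE = "non-monotone"
SIGN_CHANGE = "sign-change"
CONSTANT = "constant"


@dataclass(frozen=True)
class FseofConfig:
    """Scan settings.

    ``max_fraction`` caps the last enforcement step at that fraction of
    the theoretical maximum product flux (enforcing the full maximum would
    pin growth to zero); ``epsilon`` is the tolerance for "non-decreasing"
    and "strictly increased overall".
    """

    product_exchange: str
    biomass_reaction: str | None = None
    n_steps: int = 10
    max_fraction: float = 0.9
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.max_fraction <= 1):
            raise ValueError("max_fraction must be in (0, 1]")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


@dataclass
class FseofProfile:
    """Per-reaction flux trajectories over the enforcement grid."""

    enforced_fluxes: list[float]
    max_product_flux: float
    fluxes: dict[str, list[float]]
    classification: dict[str, str]
    biomass_values: list[float] = field(default_factory=list)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for rid in sorted(self.fluxes):
            row: dict[str, object] = {"reaction": rid, "class": self.classification[rid]}
            for k, v in enumerate(self.fluxes[rid]):
                row[f"step_{k + 1}"] = v
            rows.append(row)
        return rows


def theoretical_max_product(model: MetabolicModel, product_exchange: str) -> float:
    """Maximum product secretion flux with the biomass flux fixed to zero."""
    if product_exchange not in model.reactions:
        raise FbaError(f"unknown product exchange {product_exchange!r}")
    pinned = set_bounds(model, model.objective_reaction, 0.0, 0.0)
    result = fba(pinned, objective=product_exchange, direction="max")
    if not result.ok:
        raise FbaError(
            f"max-product stage is {result.status} for {product_exchange!r}"
        )
    return result.objective_value


def fseof_scan(model: MetabolicModel, config: FseofConfig) -> FseofProfile:
    """Run the two-stage enforced-objective-flux scan."""
    biomass = config.biomass_reaction or model.objective_reaction
    base = fba(model, objective=biomass)
    if not base.ok or base.objective_value <= GROWTH_THRESHOLD:
        raise FbaError(
            "FSEOF requires a growing base model "
            f"(status {base.status}, mu {base.objective_value!r})"
        )
    v_max = theoretical_max_product(model, config.product_exchange)
    grid = [
        (k / config.n_steps) * config.max_fraction * v_max
        for k in range(1, config.n_steps + 1)
    ]
    rxn_ids = sorted(model.reactions)
    trajectories: dict[str, list[float]] = {rid: [] for rid in rxn_ids}
    biomass_values: list[float] = []
    for k, enforced in enumerate(grid, start=1):
        stepped = set_bounds(
            model,
            config.product_exchange,
            enforced,
            max(model.reactions[config.product_exchange].upper_bound, enforced),
        )
        result = pfba(stepped, objective=biomass)
        if not result.ok:
            raise FbaError(
                f"FSEOF step {k}/{config.n_steps} (enforced flux "
                f"{enforced:.6g}) is {result.status}; lower max_fraction"
            )
        biomass_values.append(result.objective_value)
        for rid in rxn_ids:
            trajectories[rid].append(result.fluxes[rid])
    classification = {
        rid: _classify(traj, config.epsilon) for rid, traj in trajectories.items()
    }
    return FseofProfile(
        enforced_fluxes=grid,
        max_product_flux=v_max,
        fluxes=trajectories,
        classification=classification,
        biomass_values=biomass_values,
    )


def _classify(traj: list[float], eps: float) -> str:
    has_pos = any(v > eps for v in traj)
    has_neg = any(v < -eps for v in traj)
    if has_pos and has_neg:
        return SIGN_CHANGE
    mags = [abs(v) for v in traj]
    if max(mags) - min(mags) <= eps:
        return CONSTANT
    nondecreasing = all(b >= a - eps for a, b in zip(mags, mags[1:]))
    if nondecreasing and mags[-1] - mags[0] > eps:
        return AMPLIFICATION_TARGET
    return NON_MONOTONE


def amplification_targets(
    profile: FseofProfile, exclude: set[str] = frozenset()
) -> list[str]:
    """Amplification candidates, strongest first.

    Ranked by relative flux increase across the scan (|v_last| / |v_first|,
    descending; reactions switched on from zero rank first).  ``exclude``
    removes reactions that rise by construction (the product exchange and,
    typically, its transport chain).
    """
    scored: list[tuple[float, str]] = []
    for rid, traj in profile.fluxes.items():
        if profile.classification[rid] != AMPLIFICATION_TARGET or rid in exclude:
            continue
        first, last = abs(traj[0]), abs(traj[-1])
        ratio = float("inf") if first <= 1e-12 else last / first
        scored.append((ratio, rid))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [rid for _, rid in scored]
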