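"""The LP core: FBA, pFBA, FVA, blocked reactions, media."""

import numpy as np
import pytest

from gsmforge.fba import (
    FbaError,
    MediumSpec,
    apply_medium,
    blocked_reactions,
    fba,
    fva,
    pfba,
    simulate_substrate_growth,
)
from gsmforge.model import MetabolicModel, Metabolite, Reaction, ReactionKind

from oracles import random_network, vertex_enumeration_max


def _mk(reactions, objective, compartments=("c",)):
    mets = {}
    for r in reactions:
        for mid in r.stoichiometry:
            mets.setdefault(mid, Metabolite(mid, "c"))
    m = MetabolicModel(
        id="t",
        compartments={c: c for c in compartments},
        metabolites=mets,
        reactions={r.id: r for r in reactions},
        genes=set(),
        objective_reaction=objective,
    )
    m.validate()
    return m


def _chain(uptake=10.0):
    return _mk(
        [
            Reaction("EX_A", {"a": -1}, -uptake, 1000, kind=ReactionKind.EXCHANGE),
            Reaction("V1", {"a": -1, "b": 1}, 0, 1000),
            Reaction("BIO", {"b": -1}, 0, 1000, kind=ReactionKind.BIOMASS),
        ],
        "BIO",
    )


def _two_routes():
    return _mk(
        [
            Reaction("EX_A", {"a": -1}, -10, 1000, kind=ReactionKind.EXCHANGE),
            Reaction("GOOD", {"a": -1, "b": 1}, 0, 1000),
            Reaction("POOR", {"a": -1, "b": 0.5}, 0, 1000),
            Reaction("BIO", {"b": -1}, 0, 1000, kind=ReactionKind.BIOMASS),
        ],
        "BIO",
    )


class TestFba:
    def test_uptake_limited_chain(self):
        result = fba(_chain())
        assert result.ok
        assert result.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_two_routes_picks_the_better_yield(self):
        result = pfba(_two_routes())
        assert result.objective_value == pytest.approx(10.0, abs=1e-6)
        assert result.fluxes["POOR"] == pytest.approx(0.0, abs=1e-6)

    def test_no_uptake_means_zero_growth(self):
        model = _chain()
        model.reactions["EX_A"] = Reaction(
            "EX_A", {"a": -1}, 0, 1000, kind=ReactionKind.EXCHANGE
        )
        result = fba(model)
        assert result.ok and result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_objective_raises(self):
        with pytest.raises(FbaError, match="nope"):
            fba(_chain(), objective="nope")

    def test_toy_model_matches_analytic_growth(self, toy_model, toy_truth):
        assert fba(toy_model).objective_value == pytest.approx(
            toy_truth.analytic_mu, abs=1e-7
        )

    def test_homogeneity_without_maintenance(self):
        """Scaling the uptake bound scales µ identically (LP homogeneity)."""
        for k in (0.5, 2.0, 7.0):
            assert fba(_chain(uptake=10 * k)).objective_value == pytest.approx(
                10 * k, abs=1e-8
            )

    def test_mu_concave_nondecreasing_in_uptake_with_ngam(self, glucose_medium):
        from dataclasses import replace

        from gsmforge.synth import ToyModelSpec, make_toy_model

        model, _ = make_toy_model(ToyModelSpec(nutrient_cap=None))
        uptakes = [1.0, 2.0, 4.0, 6.0, 8.0]
        mus = []
        for u in uptakes:
            medium = replace(glucose_medium, uptake_rate=u)
            mus.append(fba(apply_medium(model, medium)).objective_value)
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))
        # concavity: second differences non-positive on the even grid
        diffs = np.diff(mus) / np.diff(uptakes)
        assert all(b <= a + 1e-9 for a, b in zip(diffs, diffs[1:]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_lp_optimum_matches_vertex_enumeration(self, seed):
        """On tiny random networks the HiGHS optimum equals the exhaustive
        vertex-enumeration maximum (the acceptance run sweeps 50 seeds)."""
        S, lb, ub, c = random_network(seed)
        oracle = vertex_enumeration_max(S, lb, ub, c)
        rxns = [
            Reaction(f"R{j}", {f"m{i}": S[i, j] for i in range(S.shape[0]) if S[i, j]},
                     lb[j], ub[j])
            for j in range(S.shape[1])
        ]
        # reactions touching no metabolite are free fluxes; model them with
        # a dummy metabolite cycle so validation passes
        model = _mk(
            [r if r.stoichiometry else Reaction(r.id, {"free": 0.0}, r.lower_bound, r.upper_bound)
             for r in rxns],
            rxns[int(np.argmax(c))].id,
        )
        result = fba(model, objective=f"R{int(np.argmax(c))}")
        assert oracle is not None and result.ok
        assert result.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_two_route_network_against_oracle(self):
        # EX_A, GOOD, POOR, BIO in the column order of sorted ids
        model = _two_routes()
        rxn_ids = sorted(model.reactions)
        mets = sorted(model.metabolites)
        S = np.zeros((len(mets), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in model.reactions[rid].stoichiometry.items():
                S[mets.index(mid), j] = coeff
        lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
        c = np.array([1.0 if r == "BIO" else 0.0 for r in rxn_ids])
        assert vertex_enumeration_max(S, lb, ub, c) == pytest.approx(10.0, abs=1e-9)


class TestFva:
    def test_blocked_dead_end_is_zero_zero(self, toy_model):
        lo, hi = fva(toy_model, ["DEAD1"])["DEAD1"]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_chain_flux_fixed_at_full_objective(self):
        ranges = fva(_chain(), ["V1"], objective_fraction=1.0)
        lo, hi = ranges["V1"]
        assert lo == pytest.approx(10.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    def test_fva_brackets_fba_fluxes(self, toy_model):
        result = fba(toy_model)
        ranges = fva(toy_model, objective_fraction=1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= result.fluxes[rid] <= hi + 1e-6, rid

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(FbaError, match="nope"):
            fva(toy_model, ["nope"])


class TestBlocked:
    def test_planted_dead_ends_and_stub_detected(self, toy_model, toy_truth):
        assert blocked_reactions(toy_model) == toy_truth.blocked_reactions

    def test_consistent_network_has_no_blocked_core(self, toy_model):
        blocked = blocked_reactions(toy_model)
        for rid in ("GLYC", "PYROX", "OXPHOS", "BIOMASS", "ATPM", "LDH"):
            assert rid not in blocked

    def test_isolated_reversible_cycle_not_blocked(self):
        model = _mk(
            [
                Reaction("R1", {"a": -1, "b": 1}, -1000, 1000),
                Reaction("R2", {"a": -1, "b": 1}, -1000, 1000),
            ],
            "R1",
        )
        assert blocked_reactions(model) == set()


class TestMedium:
    def test_glucose_medium_bounds(self, toy_model, glucose_medium):
        out = apply_medium(toy_model, glucose_medium)
        assert out.reactions["EX_glc_e"].lower_bound == -10
        assert out.reactions["EX_lac_e"].lower_bound == 0
        assert out.reactions["EX_o2_e"].lower_bound == -1000
        assert out.reactions["EX_h2o_e"].lower_bound == -1000

    def test_apply_medium_is_idempotent(self, toy_model, glucose_medium):
        once = apply_medium(toy_model, glucose_medium)
        twice = apply_medium(once, glucose_medium)
        for rid in once.reactions:
            assert once.reactions[rid].lower_bound == twice.reactions[rid].lower_bound

    def test_unknown_exchange_rejected(self, toy_model):
        with pytest.raises(FbaError, match="EX_nope"):
            apply_medium(toy_model, MediumSpec(carbon_source="EX_nope"))


class TestSubstrateGrowth:
    def test_growth_calls_on_toy_substrates(self, toy_model, glucose_medium):
        calls = simulate_substrate_growth(
            toy_model, {"glucose": "EX_glc_e", "erythritol": "EX_eryth_e"},
            glucose_medium,
        )
        assert calls.calls == {"glucose": True, "erythritol": False}
        assert calls.provenance == "simulated"

    def test_missing_exchange_called_no_growth_with_reason(
        self, toy_model, glucose_medium
    ):
        calls = simulate_substrate_growth(
            toy_model, {"xylose": "EX_xyl_e"}, glucose_medium
        )
        assert calls.calls == {"xylose": False}
        assert "EX_xyl_e" in calls.reasons["xylose"]

    def test_order_independence(self, toy_model, glucose_medium):
        subs = {"a": "EX_glc_e", "b": "EX_eryth_e", "c": "EX_nut_e"}
        fwd = simulate_substrate_growth(toy_model, subs, glucose_medium)
        rev = simulate_substrate_growth(
            toy_model, dict(reversed(list(subs.items()))), glucose_medium
        )
        assert fwd.calls == rev.calls

    def test_empty_substrate_list(self, toy_model, glucose_medium):
        calls = simulate_substrate_growth(toy_model, {}, glucose_medium)
        assert calls.calls == {}


class TestCobraCrossCheck:
    def test_growth_rate_agrees_with_cobrapy(self, toy_model, toy_truth, tmp_path):
        """Independent route: the same SBML file solved by COBRApy/GLPK must
        reach the same optimum as the scipy-based core."""
        import cobra

        from gsmforge.sbml_io import write_sbml

        path = tmp_path / "toy.xml"
        write_sbml(toy_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        mu = cm.optimize().objective_value
        assert mu == pytest.approx(toy_truth.analytic_mu, abs=1e-6)
        assert mu == pytest.approx(fba(toy_model).objective_value, abs=1e-6)
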