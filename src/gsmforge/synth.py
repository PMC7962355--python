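"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (spec, seed): identical inputs give
byte-identical serialized artifacts, and each generator returns the
planted ground truth alongside the artifact so recovery can be asserted
exactly.

The toy reference model is a three-compartment (extracellular, cytosol,
mitochondrion) network around a glycolysis-like trunk: glucose is split
to pyruvate with ATP and redox-carrier reduction, pyruvate is respired in
the mitochondrion, oxidative phosphorylation regenerates ATP, and a
biomass pseudo-reaction drains pyruvate, ATP and a capped auxiliary
nutrient.  Currency metabolites carry deliberately simple pseudo-element
formulas (adenosine moiety "A", redox carrier "N", nutrient "X") chosen
so that every template reaction is exactly mass- and charge-balanced.
GPR templates cover the structures homolog rewriting must preserve:
single genes, isoenzyme pairs, two-gene complexes and a nested
complex-or-isoenzyme rule.  A lactate branch provides the enforced
product for FSEOF scans, planted dead-end reactions provide deletable
orphans, and an erythritol uptake stub without catabolism drives the
add-missing-pathway workflow.

With glucose uptake u, maintenance flux n and no nutrient cap the
analytic optimum of the toy model is µ = (26·u − n)/30: each glucose
yields 2 pyruvate, 2 ATP and 2 NADH, each respired pyruvate 5 NADH, each
NADH 2 ATP, and biomass costs 1 pyruvate + 20 ATP per unit.  The capped
nutrient (1 per biomass unit) limits growth to the cap when the cap is
smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gsmforge.fba import MediumSpec
from gsmforge.gpr import GprExpression
from gsmforge.homology import HomologMap
from gsmforge.model import MetabolicModel, Metabolite, Reaction, ReactionKind
from gsmforge.phenotype import PmPlate, WellReading
from gsmforge.validation import GrowthRatePair


class GenerationError(ValueError):
    """A fixture request is contradictory or unachievable."""


L = GprExpression.leaf
AND = GprExpression.all_of
OR = GprExpression.any_of


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the generated reference model.

    ``ngam`` is the non-growth-associated maintenance flux (lower bound of
    the ATP-maintenance reaction, mmol/gDW/h); ``nutrient_cap`` the uptake
    cap of the auxiliary biomass nutrient (use ``None`` for uncapped, which
    makes growth purely carbon/energy-limited); ``n_dead_ends`` plants that
    many dead-end reactions (0-2).
    """

    seed: int = 0
    glucose_uptake: float = 10.0
    ngam: float = 1.0
    nutrient_cap: float | None = 2.0
    n_dead_ends: int = 2
    include_lactate: bool = True
    include_low_yield_branch: bool = True
    include_erythritol_stub: bool = True


@dataclass
class PlantedTruth:
    """Ground truth recorded by a generator, fields filled as relevant."""

    analytic_mu: float | None = None
    blocked_reactions: set[str] = field(default_factory=set)
    dead_end_reactions: set[str] = field(default_factory=set)
    # homology fixtures
    mapped_genes: dict[str, str] = field(default_factory=dict)
    covered_genes: set[str] = field(default_factory=set)
    sole_catalyst_genes: set[str] = field(default_factory=set)
    sole_catalyst_reactions: set[str] = field(default_factory=set)
    orphan_fates: dict[str, str] = field(default_factory=dict)
    # plate fixtures
    metabolized_substrates: set[str] = field(default_factory=set)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    # FSEOF fixtures
    fseof_targets: set[str] = field(default_factory=set)
    fseof_excluded: set[str] = field(default_factory=set)
    fseof_competing: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------
# toy reference model
# ---------------------------------------------------------------------

def _met(mid: str, comp: str, formula: str) -> Metabolite:
    return Metabolite(id=mid, compartment=comp, formula=formula)


def make_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> tuple[MetabolicModel, PlantedTruth]:
    """Build the deterministic toy reference model and its planted truth."""
    if not (0 <= spec.n_dead_ends <= 2):
        raise GenerationError("n_dead_ends must be 0, 1 or 2")
    if spec.glucose_uptake <= 0 or spec.ngam < 0:
        raise GenerationError("glucose_uptake must be > 0 and ngam >= 0")

    compartments = {"e": "extracellular", "c": "cytosol", "m": "mitochondrion"}
    mets: list[Metabolite] = [
        _met("glc_e", "e", "C6H12O6"),
        _met("glc_c", "c", "C6H12O6"),
        _met("pyr_c", "c", "C3H4O3"),
        _met("pyr_m", "m", "C3H4O3"),
        _met("nad_c", "c", "N"),
        _met("nad_m", "m", "N"),
        _met("nadh_c", "c", "H2N"),
        _met("nadh_m", "m", "H2N"),
        _met("atp_c", "c", "AHO3P"),
        _met("adp_c", "c", "A"),
        _met("pi_c", "c", "H3O4P"),
        _met("o2_e", "e", "O2"),
        _met("o2_m", "m", "O2"),
        _met("co2_m", "m", "CO2"),
        _met("co2_e", "e", "CO2"),
        _met("h2o_e", "e", "H2O"),
        _met("h2o_c", "c", "H2O"),
        _met("h2o_m", "m", "H2O"),
        _met("nut_e", "e", "X"),
        _met("nut_c", "c", "X"),
    ]

    nut_lb = -1000.0 if spec.nutrient_cap is None else -spec.nutrient_cap
    rxns: list[Reaction] = [
        Reaction("EX_glc_e", {"glc_e": -1}, -spec.glucose_uptake, 1000,
                 kind=ReactionKind.EXCHANGE),
        Reaction("EX_o2_e", {"o2_e": -1}, -1000, 1000, kind=ReactionKind.EXCHANGE),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, 1000, kind=ReactionKind.EXCHANGE),
        Reaction("EX_h2o_e", {"h2o_e": -1}, -1000, 1000, kind=ReactionKind.EXCHANGE),
        Reaction("EX_nut_e", {"nut_e": -1}, nut_lb, 1000, kind=ReactionKind.EXCHANGE),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gpr=L("gT1")),
        Reaction(
            "GLYC",
            {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
             "pyr_c": 2, "atp_c": 2, "h2o_c": 2, "nadh_c": 2},
            0, 1000, gpr=OR(L("gG1"), L("gG2")),
        ),
        Reaction("PYRt", {"pyr_c": -1, "pyr_m": 1}, 0, 1000,
                 gpr=AND(L("gC1"), L("gC2"))),
        Reaction(
            "PYROX",
            {"pyr_m": -1, "h2o_m": -3, "nad_m": -5, "co2_m": 3, "nadh_m": 5},
            0, 1000, gpr=OR(AND(L("gP1"), L("gP2")), L("gP3")),
        ),
        Reaction(
            "NADHt",
            {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
            0, 1000, gpr=OR(L("gS1"), L("gS2")),
        ),
        Reaction(
            "OXPHOS",
            {"nadh_m": -1, "o2_m": -0.5, "adp_c": -2, "pi_c": -2,
             "nad_m": 1, "h2o_m": 3, "atp_c": 2},
            0, 1000, gpr=AND(L("gO1"), L("gO2")),
        ),
        Reaction("O2t", {"o2_e": -1, "o2_m": 1}, 0, 1000, gpr=L("gX1")),
        Reaction("CO2t", {"co2_m": -1, "co2_e": 1}, 0, 1000, gpr=L("gX2")),
        Reaction("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000),
        Reaction("H2Otm", {"h2o_c": -1, "h2o_m": 1}, -1000, 1000),
        Reaction("NUTt", {"nut_e": -1, "nut_c": 1}, 0, 1000, gpr=L("gN1")),
        Reaction(
            "ATPM",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
            spec.ngam, 1000, kind=ReactionKind.MAINTENANCE,
        ),
        Reaction(
            "BIOMASS",
            {"pyr_c": -1, "atp_c": -20, "h2o_c": -20, "nut_c": -1,
             "adp_c": 20, "pi_c": 20},
            0, 1000, kind=ReactionKind.BIOMASS,
        ),
    ]

    truth = PlantedTruth()
    if spec.include_low_yield_branch:
        rxns.append(
            Reaction(
                "GLYC2",
                {"glc_c": -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2},
                0, 1000, gpr=L("gG3"),
            )
        )
    if spec.include_lactate:
        mets += [_met("lac_c", "c", "C3H6O3"), _met("lac_e", "e", "C3H6O3")]
        rxns += [
            Reaction(
                "LDH",
                {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
                0, 1000, gpr=L("gL1"),
            ),
            Reaction("LACt", {"lac_c": -1, "lac_e": 1}, 0, 1000, gpr=L("gL2")),
            Reaction("EX_lac_e", {"lac_e": -1}, 0, 1000, kind=ReactionKind.EXCHANGE),
        ]
        truth.fseof_targets = {"GLCt", "GLYC", "LDH", "LACt"}
        truth.fseof_excluded = {"EX_glc_e", "EX_lac_e"}
        truth.fseof_competing = {"PYRt", "PYROX"}
    if spec.include_erythritol_stub:
        mets += [_met("eryth_e", "e", "C4H10O4"), _met("eryth_c", "c", "C4H10O4")]
        rxns += [
            Reaction("EX_eryth_e", {"eryth_e": -1}, 0, 1000,
                     kind=ReactionKind.EXCHANGE),
            Reaction("ERYTHt", {"eryth_e": -1, "eryth_c": 1}, 0, 1000,
                     gpr=L("gE1")),
        ]
        truth.blocked_reactions |= {"EX_eryth_e", "ERYTHt"}
    for i in range(spec.n_dead_ends):
        mid = f"dead{i + 1}_c"
        mets.append(_met(mid, "c", "C3H4O3"))
        rxns.append(
            Reaction(f"DEAD{i + 1}", {"pyr_c": -1, mid: 1}, 0, 1000,
                     gpr=L(f"gD{i + 1}"))
        )
        truth.blocked_reactions.add(f"DEAD{i + 1}")
        truth.dead_end_reactions.add(f"DEAD{i + 1}")

    genes = set().union(*(r.gpr.genes() for r in rxns)) if rxns else set()
    model = MetabolicModel(
        id=f"toy_ref_seed{spec.seed}",
        compartments=compartments,
        metabolites={m.id: m for m in mets},
        reactions={r.id: r for r in rxns},
        genes=genes,
        objective_reaction="BIOMASS",
    )
    model.validate()
    energy_mu = (26 * spec.glucose_uptake - spec.ngam) / 30
    truth.analytic_mu = (
        energy_mu if spec.nutrient_cap is None else min(spec.nutrient_cap, energy_mu)
    )
    return model, truth


def default_medium(carbon_exchange: str = "EX_glc_e", uptake: float = 10.0) -> MediumSpec:
    """The toy model's minimal medium: glucose + O2 + nutrient, free water."""
    return MediumSpec(
        carbon_source=carbon_exchange,
        uptake_rate=uptake,
        free_exchanges=frozenset({"EX_h2o_e"}),
        uptake_exchanges=frozenset({"EX_o2_e", "EX_nut_e"}),
    )


def erythritol_pathway() -> tuple[list[Reaction], list[Metabolite], set[str]]:
    """The four-step erythritol catabolism (kinase, dehydrogenase,
    epimerase, aldolase splitting to dihydroxyacetone phosphate plus
    formaldehyde) with the two oxidations connecting both products to the
    toy network.  Adding it to a model carrying the erythritol uptake stub
    turns erythritol from a no-growth into a growth substrate."""
    mets = [
        _met("e1p_c", "c", "C4H11O7P"),
        _met("leru1p_c", "c", "C4H9O7P"),
        _met("eru1p_c", "c", "C4H9O7P"),
        _met("dhap_c", "c", "C3H7O6P"),
        _met("fald_c", "c", "CH2O"),
        _met("co2_c", "c", "CO2"),
    ]
    rxns = [
        Reaction("ERYTHK", {"eryth_c": -1, "atp_c": -1, "e1p_c": 1, "adp_c": 1},
                 0, 1000, gpr=L("gEK1")),
        Reaction("ERYTHDH", {"e1p_c": -1, "nad_c": -1, "leru1p_c": 1, "nadh_c": 1},
                 0, 1000, gpr=L("gED1")),
        Reaction("ERYTHEPI", {"leru1p_c": -1, "eru1p_c": 1}, 0, 1000, gpr=L("gEE1")),
        Reaction("ERYTHALD", {"eru1p_c": -1, "dhap_c": 1, "fald_c": 1},
                 0, 1000, gpr=L("gEA1")),
        Reaction(
            "DHAPOX",
            {"dhap_c": -1, "h2o_c": -1, "nad_c": -1,
             "pyr_c": 1, "pi_c": 1, "nadh_c": 1},
            0, 1000, gpr=L("gEA2"),
        ),
        Reaction(
            "FALDOX",
            {"fald_c": -1, "h2o_c": -1, "nad_c": -2, "co2_c": 1, "nadh_c": 2},
            0, 1000, gpr=L("gEA3"),
        ),
        Reaction("CO2tc", {"co2_c": -1, "co2_e": 1}, 0, 1000),
    ]
    new_genes = {"gEK1", "gED1", "gEE1", "gEA1", "gEA2", "gEA3"}
    return rxns, mets, new_genes


# ---------------------------------------------------------------------
# homolog fixtures
# ---------------------------------------------------------------------

#: single-point-of-failure genes of the toy model: unmapping one of these
#: empties exactly the named reaction's GPR
_SOLE_POOL = {
    "gT1": "GLCt", "gG3": "GLYC2", "gX1": "O2t", "gX2": "CO2t",
    "gN1": "NUTt", "gL1": "LDH", "gL2": "LACt", "gE1": "ERYTHt",
    "gD1": "DEAD1", "gD2": "DEAD2",
    "gC1": "PYRt", "gO1": "OXPHOS",
}
#: OR-redundancy groups: at most one gene per group may be unmapped while
#: leaving the reaction's GPR satisfiable
_COVERED_GROUPS = [
    ("GLYC", ("gG1", "gG2")),
    ("NADHt", ("gS1", "gS2")),
    ("PYROX", ("gP3", "gP1")),
]


def make_homolog_fixture(
    model: MetabolicModel,
    fraction_unmapped: float,
    n_sole_catalyst: int,
    seed: int = 0,
) -> tuple[HomologMap, PlantedTruth]:
    """Design a homolog table with a planted unmapped-gene partition.

    Exactly ``n_sole_catalyst`` reactions lose their GPR entirely; the
    remaining unmapped genes are always covered by isoenzyme alternatives.
    Mapped source genes translate to ``OP_<source>``.
    """
    if not (0 <= fraction_unmapped <= 1):
        raise GenerationError("fraction_unmapped must be in [0, 1]")
    genes = sorted(model.genes)
    n_unmapped = round(fraction_unmapped * len(genes))

    if fraction_unmapped == 1.0:
        # degenerate design: every gene unmapped, every GPR empties
        truth = PlantedTruth(
            sole_catalyst_genes=set(genes),
            sole_catalyst_reactions={
                r.id for r in model.reactions.values() if not r.gpr.is_empty
            },
        )
        return HomologMap({}), truth

    if n_unmapped < n_sole_catalyst:
        raise GenerationError(
            f"cannot plant {n_sole_catalyst} sole catalysts within "
            f"{n_unmapped} unmapped genes"
        )
    rng = np.random.default_rng(seed)
    sole_pool = [(g, r) for g, r in sorted(_SOLE_POOL.items()) if g in model.genes
                 and r in model.reactions]
    if n_sole_catalyst > len(sole_pool):
        raise GenerationError(
            f"requested {n_sole_catalyst} sole catalysts but only "
            f"{len(sole_pool)} single-point-of-failure genes exist"
        )
    order = rng.permutation(len(sole_pool))
    sole_genes: set[str] = set()
    sole_rxns: set[str] = set()
    for idx in order:
        if len(sole_genes) == n_sole_catalyst:
            break
        g, r = sole_pool[idx]
        if r in sole_rxns:
            continue
        sole_genes.add(g)
        sole_rxns.add(r)
    if len(sole_genes) < n_sole_catalyst:
        raise GenerationError("not enough distinct reactions for sole catalysts")

    n_covered = n_unmapped - n_sole_catalyst
    groups = [
        (rxn, members)
        for rxn, members in _COVERED_GROUPS
        if rxn in model.reactions and rxn not in sole_rxns
    ]
    if n_covered > len(groups):
        raise GenerationError(
            f"cannot plant {n_covered} alternative-covered genes: only "
            f"{len(groups)} isoenzyme groups available"
        )
    covered_genes: set[str] = set()
    for idx in rng.permutation(len(groups))[:n_covered]:
        rxn, members = groups[idx]
        covered_genes.add(members[int(rng.integers(len(members)))])

    unmapped = sole_genes | covered_genes
    mapping = {g: f"OP_{g}" for g in genes if g not in unmapped}
    truth = PlantedTruth(
        mapped_genes=mapping,
        covered_genes=covered_genes,
        sole_catalyst_genes=sole_genes,
        sole_catalyst_reactions=sole_rxns,
        orphan_fates={
            r: ("deleted" if r in ("DEAD1", "DEAD2", "ERYTHt") else "retained")
            for r in sole_rxns
        },
    )
    return HomologMap(mapping), truth


def write_homolog_tsv(
    homologs: HomologMap, source_genes, path: str
) -> None:
    """Serialize as a two-column TSV with ``*`` marking missing homologs."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for g in sorted(source_genes):
            fh.write(f"{g}\t{homologs.mapping.get(g, '*')}\n")


# ---------------------------------------------------------------------
# phenotype-plate fixtures
# ---------------------------------------------------------------------

def make_pm_fixture(
    n_wells: int = 96,
    planted_positives: int = 10,
    bulk_mean: float = 0.05,
    bulk_sd: float = 0.01,
    effect_sizes: float | list[float] = 10.0,
    n_replicates: int = 3,
    seed: int = 0,
    clip_negative: bool = True,
    plate_id: str = "PM1",
) -> tuple[list[PmPlate], PlantedTruth]:
    """Generate replicate phenotype plates with planted metabolized wells.

    Bulk wells draw ΔOD from Normal(bulk_mean, bulk_sd) (clipped at 0 by
    default, matching the non-negative dye signal); each planted positive
    well is offset by its effect size × bulk_sd.  OD(t0) is drawn
    uniformly in a small band and OD(t_end) = OD(t0) + ΔOD, so the
    designed deltas survive the round trip exactly.
    """
    if planted_positives >= n_wells:
        raise GenerationError("planted_positives must be < n_wells")
    if isinstance(effect_sizes, (int, float)):
        effect_sizes = [float(effect_sizes)] * planted_positives
    if len(effect_sizes) != planted_positives:
        raise GenerationError("one effect size per planted positive required")
    rng = np.random.default_rng(seed)
    substrates = [f"S{i + 1:03d}" for i in range(n_wells)]
    positives = sorted(rng.choice(n_wells, size=planted_positives, replace=False))
    effect_by_well = dict(zip(positives, effect_sizes))

    plates: list[PmPlate] = []
    for rep in range(1, n_replicates + 1):
        deltas = rng.normal(bulk_mean, bulk_sd, size=n_wells)
        if clip_negative:
            deltas = np.clip(deltas, 0.0, None)
        for w, eff in effect_by_well.items():
            deltas[w] = rng.normal(bulk_mean + eff * bulk_sd, bulk_sd)
        od0_dye = rng.uniform(0.05, 0.15, size=n_wells)
        od0_bio = rng.uniform(0.10, 0.20, size=n_wells)
        wells: dict[str, dict[int, WellReading]] = {}
        for i, sub in enumerate(substrates):
            growth_od = 0.3 if i in effect_by_well else 0.0
            wells[f"W{i + 1:03d}"] = {
                490: WellReading(sub, float(od0_dye[i]), float(od0_dye[i] + deltas[i])),
                750: WellReading(sub, float(od0_bio[i]), float(od0_bio[i] + growth_od)),
            }
        plates.append(PmPlate(plate_id=plate_id, replicate=rep, wells=wells))

    truth = PlantedTruth(
        metabolized_substrates={substrates[w] for w in positives},
        effect_sizes={substrates[w]: e for w, e in effect_by_well.items()},
    )
    return plates, truth


# ---------------------------------------------------------------------
# growth-rate pair fixtures
# ---------------------------------------------------------------------

def make_growth_rate_pairs(
    model: MetabolicModel,
    substrate_exchanges: dict[str, str],
    base_medium: MediumSpec,
    n_per_substrate: int = 3,
    uptake_range: tuple[float, float] = (2.0, 10.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[GrowthRatePair]:
    """Emulate literature (uptake, growth-rate) observations.

    Measured µ = simulated µ at a drawn uptake rate plus truncated
    Gaussian noise; with ``noise_sd`` 0 the correlation between measured
    and re-simulated rates is exactly 1.
    """
    from dataclasses import replace as _replace

    from gsmforge.fba import apply_medium, fba

    rng = np.random.default_rng(seed)
    pairs: list[GrowthRatePair] = []
    for name in sorted(substrate_exchanges):
        ex = substrate_exchanges[name]
        for k in range(n_per_substrate):
            uptake = float(rng.uniform(*uptake_range))
            medium = _replace(base_medium, carbon_source=ex, uptake_rate=uptake)
            result = fba(apply_medium(model, medium))
            mu = result.objective_value if result.ok else 0.0
            measured = max(0.0, mu + float(rng.normal(0.0, noise_sd)))
            pairs.append(
                GrowthRatePair(
                    substrate=name,
                    uptake_rate=uptake,
                    growth_rate=measured,
                    source=f"synthetic:seed{seed}:{k}",
                )
            )
    return pairs
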