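"""Materialize a complete synthetic reconstruction study on disk."""

from pathlib import Path

from gsmforge.phenotype import write_plates_csv
from gsmforge.pipeline import PipelineConfig
from gsmforge.sbml_io import write_sbml
from gsmforge.synth import (
    ToyModelSpec,
    default_medium,
    make_growth_rate_pairs,
    make_homolog_fixture,
    make_pm_fixture,
    make_toy_model,
    write_homolog_tsv,
)
from gsmforge.validation import write_pairs_csv

MEDIUM = {
    "carbon_source": "EX_glc_e",
    "free_exchanges": ["EX_h2o_e"],
    "uptake_exchanges": ["EX_o2_e", "EX_nut_e"],
}


def build_study(
    root: Path,
    seed: int = 0,
    with_plates: bool = True,
    with_pairs: bool = True,
    with_fseof: bool = True,
):
    """Write every pipeline input under ``root`` and return
    (config, truths) where ``truths`` collects each generator's planted
    ground truth keyed by stage."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    model, model_truth = make_toy_model(ToyModelSpec(seed=seed))
    ref = root / "reference.xml"
    write_sbml(model, ref)

    homologs, homolog_truth = make_homolog_fixture(model, 0.25, 2, seed=seed)
    homolog_tsv = root / "homologs.tsv"
    write_homolog_tsv(homologs, model.genes, str(homolog_tsv))

    plate_csvs: list[str] = []
    plate_truth = None
    substrate_exchanges: dict[str, str] = {}
    if with_plates:
        plates, plate_truth = make_pm_fixture(seed=seed)
        plate_csv = root / "plates.csv"
        write_plates_csv(plates, str(plate_csv))
        plate_csvs = [str(plate_csv)]
        # tie one metabolized and one bulk substrate to model exchanges;
        # the rest of the plate has no model counterpart and is dropped
        positive = sorted(plate_truth.metabolized_substrates)[0]
        all_subs = {plates[0].substrate_of(w) for w in plates[0].wells}
        negative = sorted(all_subs - plate_truth.metabolized_substrates)[0]
        substrate_exchanges = {positive: "EX_glc_e", negative: "EX_eryth_e"}

    pairs_csv = None
    if with_pairs:
        pairs = make_growth_rate_pairs(
            model,
            {"glucose": "EX_glc_e"},
            default_medium(),
            n_per_substrate=5,
            uptake_range=(0.5, 2.2),
            noise_sd=0.0,
            seed=seed,
        )
        pairs_path = root / "pairs.csv"
        write_pairs_csv(pairs, str(pairs_path))
        pairs_csv = str(pairs_path)
        substrate_exchanges.setdefault("glucose", "EX_glc_e")

    config = PipelineConfig(
        reference_model=str(ref),
        homolog_table=str(homolog_tsv),
        out_dir=str(root / "out"),
        plate_csvs=plate_csvs,
        pairs_csv=pairs_csv,
        substrate_exchanges=substrate_exchanges,
        medium=dict(MEDIUM),
        fseof=(
            {"product_exchange": "EX_lac_e", "exclude": ["EX_glc_e"]}
            if with_fseof
            else None
        ),
        seed=seed,
    )
    truths = {
        "model": model_truth,
        "homology": homolog_truth,
        "plates": plate_truth,
    }
    return config, truths
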