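"""End-to-end reconstruction workflow.

Orchestrates: GPR translation from the homolog table → orphan resolution
→ balance audit → draft model output → phenotype-plate growth calling →
substrate growth simulation → confusion matrix/agreement → optional
growth-rate validation → optional FSEOF scan.  Every artifact is written
under the configured output directory and digested into a run manifest;
re-running with identical inputs reproduces identical digests.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from gsmforge import __version__
from gsmforge.fba import GROWTH_THRESHOLD, MediumSpec, simulate_substrate_growth
from gsmforge.fseof import FseofConfig, amplification_targets, fseof_scan
from gsmforge.homology import parse_homolog_table, resolve_orphans, translate_model
from gsmforge.model import check_balance
from gsmforge.phenotype import call_growth, read_plates_csv, replicate_thresholds
from gsmforge.sbml_io import read_sbml, write_sbml
from gsmforge.validation import (
    agreement,
    confusion,
    growth_rate_validation,
    read_pairs_csv,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one reconstruction run.

    ``substrate_exchanges`` maps plate substrate names to model exchange
    ids — the mapping is explicit and user-editable; names it does not
    cover are reported, never guessed.
    """

    reference_model: str
    homolog_table: str
    out_dir: str
    plate_csvs: list[str] = field(default_factory=list)
    pairs_csv: str | None = None
    substrate_exchanges: dict[str, str] = field(default_factory=dict)
    medium: dict = field(default_factory=dict)
    exclude_substrates: list[str] = field(default_factory=list)
    growth_threshold: float = GROWTH_THRESHOLD
    uptake_rate: float = 10.0
    fseof: dict | None = None  # {product_exchange, n_steps, max_fraction}
    seed: int = 0

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)

    def medium_spec(self, carbon_source: str | None = None) -> MediumSpec:
        m = dict(self.medium)
        return MediumSpec(
            carbon_source=carbon_source or m.get("carbon_source", ""),
            uptake_rate=m.get("uptake_rate", self.uptake_rate),
            free_exchanges=frozenset(m.get("free_exchanges", ())),
            uptake_exchanges=frozenset(m.get("uptake_exchanges", ())),
        )


@dataclass
class RunManifest:
    version: str
    config_digest: str
    stage_summaries: dict[str, dict]
    output_digests: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_digest": self.config_digest,
                "stage_summaries": self.stage_summaries,
                "output_digests": self.output_digests,
            },
            indent=2,
            sort_keys=True,
        )


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        if not rows:
            fh.write("")
            return
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def run_reconstruction(config: PipelineConfig) -> RunManifest:
    """Execute the workflow; stage failures abort with the stage name,
    preserving outputs already written."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries: dict[str, dict] = {}
    outputs: dict[str, Path] = {}
    log: list[dict] = []

    def note(stage: str, message: str, level: str = "info") -> None:
        log.append({"stage": stage, "level": level, "message": message})

    def run_stage(stage: str, fn):
        try:
            return fn()
        except Exception as exc:
            _write_log(out_dir, log)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # translate -------------------------------------------------------
    def _translate():
        ref = read_sbml(config.reference_model)
        homologs = parse_homolog_table(config.homolog_table)
        draft, report = translate_model(ref, homologs)
        return ref, homologs, draft, report

    ref, homologs, draft, report = run_stage("translate", _translate)
    summaries["translate"] = {
        "n_gprs_rewritten": report.n_gprs_rewritten,
        "n_unmapped_genes": len(report.unmapped_genes),
        "n_covered_by_alternatives": len(report.genes_covered_by_alternatives),
        "n_sole_catalyst_reactions": len(report.sole_catalyst_reactions),
    }
    note("translate", f"rewrote GPRs against {len(homologs)} homolog pairs")

    # orphans ---------------------------------------------------------
    def _orphans():
        return resolve_orphans(draft, report.sole_catalyst_reactions)

    resolved, resolution = run_stage("resolve_orphans", _orphans)
    report.orphan_resolution = resolution
    summaries["resolve_orphans"] = {
        "n_deleted": sum(r.action == "deleted" for r in resolution.values()),
        "n_retained": sum(r.action == "retained" for r in resolution.values()),
    }
    outputs["translation_report.json"] = out_dir / "translation_report.json"
    outputs["translation_report.json"].write_text(report.to_json())

    # balance audit ---------------------------------------------------
    balance = run_stage("check_balance", lambda: check_balance(resolved))
    summaries["check_balance"] = {
        "fraction_balanced": balance.fraction_balanced,
        **{f"n_{k}": v for k, v in sorted(balance.counts().items())},
    }
    outputs["balance_report.tsv"] = out_dir / "balance_report.tsv"
    _write_tsv(outputs["balance_report.tsv"], balance.to_rows())

    # draft model -----------------------------------------------------
    outputs["draft_model.xml"] = out_dir / "draft_model.xml"
    run_stage("write_draft", lambda: write_sbml(resolved, outputs["draft_model.xml"]))

    # phenotype plates ------------------------------------------------
    measured = None
    if config.plate_csvs:
        def _plates():
            plates = []
            for p in config.plate_csvs:
                plates.extend(read_plates_csv(p))
            calls = call_growth(plates, exclude=set(config.exclude_substrates))
            thresholds = replicate_thresholds(
                plates, exclude=set(config.exclude_substrates)
            )
            return calls, thresholds

        measured, thresholds = run_stage("call_growth", _plates)
        summaries["call_growth"] = {
            "n_substrates": len(measured.calls),
            "n_metabolized": sum(measured.calls.values()),
        }
        outputs["measured_calls.tsv"] = out_dir / "measured_calls.tsv"
        _write_tsv(outputs["measured_calls.tsv"], measured.to_rows())
        outputs["plate_thresholds.json"] = out_dir / "plate_thresholds.json"
        outputs["plate_thresholds.json"].write_text(
            json.dumps(
                {
                    k: {"truncation_mean": t.truncation_mean, "mean": t.mean,
                        "sd": t.sd, "cutoff": t.cutoff}
                    for k, t in sorted(thresholds.items())
                },
                indent=2,
                sort_keys=True,
            )
        )
    else:
        note("call_growth", "no plate CSVs configured; stage skipped", "warning")

    # substrate simulation + confusion --------------------------------
    if measured is not None and config.substrate_exchanges:
        def _simulate():
            base = config.medium_spec(
                carbon_source=next(iter(sorted(config.substrate_exchanges.values())))
            )
            predicted = simulate_substrate_growth(
                resolved,
                config.substrate_exchanges,
                base,
                uptake_rate=config.uptake_rate,
                growth_threshold=config.growth_threshold,
            )
            matrix, dropped = confusion(measured, predicted)
            frac, pct = agreement(matrix)
            return predicted, matrix, dropped, frac, pct

        predicted, matrix, dropped, frac, pct = run_stage(
            "substrate_validation", _simulate
        )
        summaries["substrate_validation"] = {
            **matrix.as_dict(),
            "agreement_fraction": frac,
            "agreement_percent": pct,
            "n_dropped": len(dropped),
        }
        outputs["predicted_calls.tsv"] = out_dir / "predicted_calls.tsv"
        _write_tsv(outputs["predicted_calls.tsv"], predicted.to_rows())
        outputs["confusion.json"] = out_dir / "confusion.json"
        outputs["confusion.json"].write_text(
            json.dumps(
                {**matrix.as_dict(), "agreement_fraction": frac,
                 "agreement_percent": pct, "dropped_substrates": dropped},
                indent=2,
                sort_keys=True,
            )
        )
    else:
        note("substrate_validation", "plates or substrate map missing; skipped",
             "warning")

    # growth-rate validation ------------------------------------------
    if config.pairs_csv:
        def _rates():
            pairs = read_pairs_csv(config.pairs_csv)
            base = config.medium_spec(
                carbon_source=next(iter(sorted(config.substrate_exchanges.values())))
            )
            simulated, r = growth_rate_validation(
                resolved, pairs, config.substrate_exchanges, base
            )
            return pairs, simulated, r

        pairs, simulated, r = run_stage("growth_rate_validation", _rates)
        summaries["growth_rate_validation"] = {
            "n_pairs": len(simulated),
            "pearson_r": r,
        }
        outputs["growth_rates.tsv"] = out_dir / "growth_rates.tsv"
        _write_tsv(
            outputs["growth_rates.tsv"],
            [
                {
                    "substrate": pairs[i].substrate,
                    "uptake_rate": pairs[i].uptake_rate,
                    "measured_mu": pairs[i].growth_rate,
                    "simulated_mu": mu,
                }
                for i, mu in sorted(simulated.items())
            ],
        )
    else:
        note("growth_rate_validation", "no pairs CSV configured; skipped", "warning")

    # FSEOF -----------------------------------------------------------
    if config.fseof:
        def _fseof():
            fcfg = FseofConfig(
                product_exchange=config.fseof["product_exchange"],
                n_steps=int(config.fseof.get("n_steps", 10)),
                max_fraction=float(config.fseof.get("max_fraction", 0.9)),
            )
            base = config.medium_spec(
                carbon_source=config.medium.get("carbon_source", "")
            )
            from gsmforge.fba import apply_medium

            scan_model = (
                apply_medium(resolved, base) if base.carbon_source else resolved
            )
            profile = fseof_scan(scan_model, fcfg)
            exclude = set(config.fseof.get("exclude", [])) | {fcfg.product_exchange}
            targets = amplification_targets(profile, exclude=exclude)
            return profile, targets

        profile, targets = run_stage("fseof", _fseof)
        summaries["fseof"] = {
            "max_product_flux": profile.max_product_flux,
            "n_targets": len(targets),
            "targets": targets,
        }
        outputs["fseof.tsv"] = out_dir / "fseof.tsv"
        _write_tsv(outputs["fseof.tsv"], profile.to_rows())
    else:
        note("fseof", "no FSEOF config; skipped", "warning")

    _write_log(out_dir, log)
    outputs["run_log.json"] = out_dir / "run_log.json"

    config_digest = hashlib.sha256(
        json.dumps(
            {k: v for k, v in sorted(vars(config).items())}, sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()
    manifest = RunManifest(
        version=__version__,
        config_digest=config_digest,
        stage_summaries=summaries,
        output_digests={name: _digest_file(path) for name, path in sorted(outputs.items())},
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _write_log(out_dir: Path, log: list[dict]) -> None:
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
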