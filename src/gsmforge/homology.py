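"""Homology-based translation of a reference model to a target organism.

A homolog table (one best target-gene candidate per source gene, as
produced by reciprocal-best-hit style tools) drives a rewrite of every
GPR: mapped genes are renamed, a missing isoenzyme leaves the OR-branch
alternatives in place, and a missing complex member removes the whole
conjunct, because the complex cannot assemble.  Reactions whose GPR
empties ("orphans": no supporting gene in the target genome) are then
resolved by flux analysis — deleted when they cannot carry flux in any
steady state, retained when they are metabolically connected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

from gsmforge.fba import blocked_reactions
from gsmforge.gpr import GprExpression
from gsmforge.model import MetabolicModel, remove_reaction

FULLY_MAPPED = "fully-mapped"
SATISFIED_BY_ALTERNATIVES = "satisfied-by-alternatives"
EMPTIED = "emptied"


class HomologTableError(ValueError):
    """Malformed or self-contradictory homolog table."""


@dataclass
class HomologMap:
    """Partial source-gene → target-gene mapping.

    At most one target per source gene; sources without a detected homolog
    are simply absent from ``mapping``.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for src, tgt in self.mapping.items():
            if not src or not tgt:
                raise HomologTableError("empty gene id in homolog map")

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def __getitem__(self, gene: str) -> str:
        return self.mapping[gene]

    def __len__(self) -> int:
        return len(self.mapping)

    @staticmethod
    def identity(genes) -> "HomologMap":
        return HomologMap({g: g for g in genes})


def parse_homolog_table(
    path: str,
    source_column: str | int = 0,
    target_column: str | int = 1,
) -> HomologMap:
    """Read a tab-separated homolog table.

    Two dialects are accepted: a simple two-column source/target file
    (with or without a header naming the columns), and the wider
    orthology-tool dialect where additional columns exist and ``*`` marks
    a missing homolog.  Duplicate rows with identical targets collapse;
    duplicate sources with conflicting targets raise, because "one best
    candidate" is the table's contract.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [row for row in reader if row and not row[0].startswith("#")]
    if not rows:
        return HomologMap({})
    header = rows[0]
    src_idx, tgt_idx = source_column, target_column
    data = rows
    if isinstance(source_column, str) or isinstance(target_column, str):
        try:
            src_idx = header.index(str(source_column))
            tgt_idx = header.index(str(target_column))
        except ValueError as exc:
            raise HomologTableError(f"missing column in header: {exc}") from exc
        data = rows[1:]
    for row in data:
        if max(src_idx, tgt_idx) >= len(row):
            raise HomologTableError(f"short row in homolog table: {row!r}")
        src, tgt = row[src_idx].strip(), row[tgt_idx].strip()
        if not src:
            continue
        if tgt in ("", "*"):
            continue  # recorded as unmapped by absence
        if src in mapping and mapping[src] != tgt:
            raise HomologTableError(
                f"conflicting targets for source gene {src!r}: "
                f"{mapping[src]!r} vs {tgt!r}"
            )
        mapping[src] = tgt
    return HomologMap(mapping)


@dataclass(frozen=True)
class GprRewriteOutcome:
    new_gpr: GprExpression
    status: str  # FULLY_MAPPED | SATISFIED_BY_ALTERNATIVES | EMPTIED


def rewrite_gpr(gpr: GprExpression, homologs: HomologMap) -> GprRewriteOutcome:
    """Rewrite one GPR under the homolog map.

    Mapped leaves are renamed to their target gene.  An unmapped leaf
    under OR removes only that branch; under AND it removes the entire
    conjunct (simplification propagates the missing complex member).  The
    result is simplified (single-child nodes collapsed, duplicates
    merged).
    """
    if gpr.is_empty:
        return GprRewriteOutcome(new_gpr=gpr, status=FULLY_MAPPED)
    rewritten = _rewrite(gpr, homologs).simplify()
    unmapped = {g for g in gpr.genes() if g not in homologs}
    if not unmapped:
        status = FULLY_MAPPED
    elif rewritten.is_empty:
        status = EMPTIED
    else:
        status = SATISFIED_BY_ALTERNATIVES
    return GprRewriteOutcome(new_gpr=rewritten, status=status)


def _rewrite(gpr: GprExpression, homologs: HomologMap) -> GprExpression:
    if gpr.op == "leaf":
        if gpr.gene in homologs:
            return GprExpression.leaf(homologs[gpr.gene])
        return GprExpression.empty()
    if gpr.op == "empty":
        return gpr
    return GprExpression(
        gpr.op, children=tuple(_rewrite(c, homologs) for c in gpr.children)
    )


@dataclass
class TranslationReport:
    """Accounting of a whole-model GPR rewrite.

    ``n_gprs_rewritten`` counts reactions whose non-empty GPR was fully
    rewritten (every gene had a homolog).  Unmapped source genes partition
    into ``genes_covered_by_alternatives`` (every reaction using them
    keeps a satisfiable GPR through isoenzymes) and sole catalysts, whose
    loss empties at least one reaction's GPR
    (``sole_catalyst_reactions``).  ``orphan_resolution`` is filled by
    :func:`resolve_orphans`.
    """

    n_gprs_rewritten: int
    unmapped_genes: set[str]
    genes_covered_by_alternatives: set[str]
    sole_catalyst_genes: set[str]
    sole_catalyst_reactions: set[str]
    rewrite_status: dict[str, str] = field(default_factory=dict)
    orphan_resolution: dict[str, "OrphanResolution"] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "n_gprs_rewritten": self.n_gprs_rewritten,
            "unmapped_genes": sorted(self.unmapped_genes),
            "genes_covered_by_alternatives": sorted(
                self.genes_covered_by_alternatives
            ),
            "sole_catalyst_genes": sorted(self.sole_catalyst_genes),
            "sole_catalyst_reactions": sorted(self.sole_catalyst_reactions),
            "orphan_resolution": {
                rid: {
                    "action": res.action,
                    "reason": res.reason,
                    "newly_blocked": sorted(res.newly_blocked),
                }
                for rid, res in sorted(self.orphan_resolution.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def translate_model(
    ref: MetabolicModel, homologs: HomologMap
) -> tuple[MetabolicModel, TranslationReport]:
    """Rewrite every GPR of the reference model into target-organism genes.

    Stoichiometry, bounds, the biomass equation and maintenance fluxes are
    copied unchanged — only the gene layer is translated.  Reactions whose
    GPR empties are collected as sole-catalyst orphans awaiting
    :func:`resolve_orphans`.
    """
    ref.validate()
    out = ref.copy()
    status_by_rxn: dict[str, str] = {}
    emptied_rxns: set[str] = set()
    n_rewritten = 0
    new_genes: set[str] = set()
    from dataclasses import replace as _replace

    for rid in sorted(ref.reactions):
        rxn = ref.reactions[rid]
        outcome = rewrite_gpr(rxn.gpr, homologs)
        status_by_rxn[rid] = outcome.status
        if outcome.status == EMPTIED:
            emptied_rxns.add(rid)
        if outcome.status == FULLY_MAPPED and not rxn.gpr.is_empty:
            n_rewritten += 1
        new_genes |= outcome.new_gpr.genes()
        out.reactions[rid] = _replace(rxn, gpr=outcome.new_gpr)
    out.genes = new_genes
    out.validate()

    unmapped = {g for g in ref.genes if g not in homologs}
    gene_to_rxns: dict[str, set[str]] = {}
    for rid, rxn in ref.reactions.items():
        for g in rxn.gpr.genes():
            gene_to_rxns.setdefault(g, set()).add(rid)
    sole_genes = {
        g
        for g in unmapped
        if gene_to_rxns.get(g, set()) & emptied_rxns
    }
    covered = {
        g for g in unmapped if g in gene_to_rxns and g not in sole_genes
    }
    report = TranslationReport(
        n_gprs_rewritten=n_rewritten,
        unmapped_genes=unmapped,
        genes_covered_by_alternatives=covered,
        sole_catalyst_genes=sole_genes,
        sole_catalyst_reactions=emptied_rxns,
        rewrite_status=status_by_rxn,
    )
    return out, report


@dataclass(frozen=True)
class OrphanResolution:
    action: str  # "deleted" | "retained"
    reason: str  # "blocked" | "gap-creating"
    newly_blocked: frozenset[str] = frozenset()


def resolve_orphans(
    model: MetabolicModel, orphans: set[str]
) -> tuple[MetabolicModel, dict[str, OrphanResolution]]:
    """Delete or retain reactions left without gene support.

    An orphan that cannot carry flux with all exchanges open is deleted
    (reason ``blocked``); a flux-carrying orphan is retained (reason
    ``gap-creating``), with the set of reactions its removal would newly
    block recorded as evidence of metabolic connectedness.  Retained
    orphans keep their empty GPR.
    """
    unknown = sorted(set(orphans) - set(model.reactions))
    if unknown:
        raise KeyError(f"unknown orphan reactions: {unknown}")
    baseline_blocked = blocked_reactions(model)
    resolution: dict[str, OrphanResolution] = {}
    out = model
    for rid in sorted(orphans):
        if rid in baseline_blocked:
            out = remove_reaction(out, rid)
            resolution[rid] = OrphanResolution(action="deleted", reason="blocked")
        else:
            without = remove_reaction(model, rid)
            newly = blocked_reactions(without) - baseline_blocked
            resolution[rid] = OrphanResolution(
                action="retained",
                reason="gap-creating",
                newly_blocked=frozenset(newly),
            )
    return out, resolution
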