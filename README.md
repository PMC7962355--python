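# gsmforge

Homology-based translation, validation and strain-design scanning for
genome-scale metabolic models.

## The scientific problem

A genome-scale metabolic model (GSMM) encodes an organism's metabolism as a
stoichiometric network with gene–protein–reaction (GPR) rules, and predicts
growth by flux balance analysis (FBA): maximize a biomass pseudo-reaction
subject to steady-state mass balance and flux bounds. Building such a model
for a new organism rarely starts from scratch. The standard route is to
*translate* a curated reference model from a related organism: a homolog
table (one best target-gene candidate per reference gene) drives a rewrite
of every GPR, and the stoichiometry is carried over unchanged.

The translation is where the biology lives:

- a missing **isoenzyme** (one branch of an OR rule) leaves the reaction
  supported by its alternatives;
- a missing **complex member** (one leaf of an AND rule) removes the whole
  conjunct, because the complex cannot assemble;
- a reaction whose entire GPR empties is an **orphan**. Orphans that cannot
  carry flux in any steady state are deleted; flux-carrying orphans are
  retained (deleting them would create metabolic gaps), with the set of
  reactions their removal would newly block recorded as evidence.

The draft model is then confronted with experiments: phenotype-microarray
plates (a tetrazolium dye read at 490 nm reports respiration per substrate
well) are thresholded into binary growth calls, compared against per-substrate
FBA simulations in a confusion matrix, and measured (uptake, growth-rate)
pairs are correlated with simulated growth rates. Finally, FSEOF (flux
scanning based on enforced objective flux) ranks overexpression candidates
for a target product: reactions whose flux rises monotonically as product
secretion is enforced in steps, while biomass is re-maximized at each step.

`gsmforge` implements this whole workflow as a library plus a `forge` CLI,
with seeded synthetic generators that plant ground truth (analytic growth
rates, known orphan fates, known metabolized substrates, known FSEOF
targets) so every stage is testable exactly.

## Worked example

Generate a seeded toy reference model and a homolog table with a planted
unmapped-gene design, then translate and scan it:

```console
$ forge synth model --seed 0 --out fixtures
wrote model fixture to fixtures
$ forge synth homologs --seed 0 --out fixtures
wrote homologs fixture to fixtures
$ forge validate-model fixtures/toy_model.xml
{
  "fraction_balanced": 1.0,
  "genes": 21,
  "metabolites": 26,
  "model": "toy_ref_seed0",
  "reactions": 26,
  "status_counts": {
    "balanced": 17,
    "exempt": 9
  }
}
$ forge translate --ref fixtures/toy_model.xml --homologs fixtures/homologs.tsv \
    --out draft.xml --report report.json
rewrote 10 GPRs; 5 unmapped genes; 2 orphan reactions
$ forge fseof draft.xml --product EX_lac_e --out fseof.tsv
amplification targets (strongest first): LACt, LDH, EX_glc_e, GLCt, GLYC
```

The translation report records each orphan's fate. Here the planted dead-end
reaction is deleted (it can carry no flux), while the glucose transporter —
whose sole gene had no homolog — is retained, with every reaction its
removal would block listed as evidence:

```json
{
  "DEAD2": {"action": "deleted", "reason": "blocked", "newly_blocked": []},
  "GLCt":  {"action": "retained", "reason": "gap-creating",
            "newly_blocked": ["ATPM", "BIOMASS", "GLYC", "..."]}
}
```

The translated draft still grows at the toy model's analytic optimum:

```pycon
>>> from gsmforge import read_sbml, fba
>>> fba(read_sbml("draft.xml")).objective_value
2.0
```

The FSEOF scan recovers the planted lactate trunk (`GLCt → GLYC → LDH →
LACt`) as amplification targets; the respiration branch (`PYRt`, `PYROX`)
loses flux and is correctly not proposed.

The full pipeline — translation, orphan resolution, balance audit, plate
growth-calling, confusion matrix, growth-rate correlation, FSEOF — runs from
one YAML config and writes a manifest of SHA-256 digests:

```bash
forge run --config run.yml
```

## Layout

- `src/gsmforge/` — model core (`model`, `gpr`, `formula`, `sbml_io`),
  LP engine (`fba`), translation (`homology`), phenotype classifier
  (`phenotype`), validation (`validation`), strain design (`fseof`),
  generators (`synth`), orchestration (`pipeline`, `cli`)
- `tests/` — unit, property (hypothesis) and acceptance tests, with
  independent oracles in `tests/oracles.py` (exhaustive vertex-enumeration
  LP, textbook Pearson, closed-form threshold calibration)
- `scripts/acceptance.py` — computes the headline quantities for a seed
- `docs/methods.md` — methods note
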