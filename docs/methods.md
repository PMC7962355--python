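# Methods

This note describes, in the package's own terms, what each stage computes,
the parameters that control it, and the numerical choices made.

## Model core

A model is a set of compartments, metabolites (with optional elemental
formula and charge), and reactions (stoichiometry, bounds, GPR rule, and a
kind: internal, exchange, demand, biomass, or maintenance). Reaction kinds
round-trip through SBML Level 3 + FBC v2 using SBO terms (627 exchange,
628 demand, 629 biomass, 630 maintenance). Serialization is deterministic:
elements are sorted by id and bounds share value-keyed parameters, so the
same model always produces byte-identical SBML.

The balance audit evaluates each internal reaction's elemental and charge
balance from metabolite formulas. Formulas use a strict `ElementCount`
grammar (Hill-order output); reactions with any unannotated participant are
reported as `unknown-formula` and excluded from the aggregate
`fraction_balanced`, as are exchange/demand/biomass/maintenance reactions
(exempt by construction, since they are intentionally unbalanced).

Model comparison counts reactions per compartment as shared / unique to
either model; a transport reaction is counted in every compartment its
participants occupy.

## FBA engine

FBA is the LP max c·v subject to S·v = 0, lb ≤ v ≤ ub, solved with
scipy's HiGHS (`method="highs"`). Parsimonious FBA (pFBA) fixes the
objective at its optimum (slack 1e-9, scaled) and minimizes Σ|v| via
variable splitting; it is used wherever a *flux vector* (not just an
objective value) is reported, because FBA optima are generically
degenerate. FVA minimizes/maximizes each flux, optionally with the
objective constrained to a fraction of its optimum.

Blocked reactions are those with FVA range within ±1e-9 of zero after
opening every exchange to ±1000. For this structural probe, enforced
fluxes on internal reactions (e.g. a maintenance lower bound) are relaxed
to admit v = 0, so the probe is never infeasible; this does not change the
blocked set of any feasible model.

A medium is a carbon-source exchange (lower bound −uptake_rate,
mmol/gDW/h, default 10), plus freely exchanged and uptake-permitted
exchanges. Opening an uptake exchange respects a model-intrinsic cap (an
already-negative lower bound is kept): the medium grants availability, it
does not lift caps. All other exchanges become secretion-only. Growth
calls from simulation use a threshold of 1e-6 h⁻¹ on the biomass optimum.

## Homology translation

The homolog table (TSV, `*` or blank = no homolog; conflicting duplicate
sources are an error) induces a GPR rewrite: mapped leaves are renamed; an
unmapped leaf under OR removes only that branch; under AND it empties the
whole conjunct. Per reaction the outcome is `fully-mapped`,
`satisfied-by-alternatives`, or `emptied`. Unmapped reference genes
partition into genes covered by alternatives and sole catalysts (genes
whose loss empties at least one reaction). Stoichiometry, bounds, biomass
and maintenance are copied unchanged.

Orphans (emptied reactions) are resolved by flux analysis: blocked →
deleted (reason `blocked`); flux-carrying → retained (reason
`gap-creating`), with the reactions its removal would newly block recorded.

## Phenotype classifier

Per well, the signal is ΔOD = OD(t_end) − OD(t0) at 490 nm (750 nm is
carried through I/O but unused). Per replicate plate: values strictly
above the plate's arithmetic mean are removed once; the retained values
are summarized by their sample mean and sample standard deviation (n−1);
the cutoff is mean + 1 sd. A well is positive when its ΔOD strictly
exceeds its own plate's cutoff; a substrate is called metabolized when at
least 50% of replicates are positive. Plate means use `math.fsum` so a
plate of identical values is not destroyed by summation round-off.

**False-positive behaviour (important).** Applied to a pure normal bulk,
truncation at the mean retains the lower half-normal, whose moments give a
cutoff at µ − 0.195σ of the bulk — *below* the bulk mean. The asymptotic
per-replicate positive rate on null wells is therefore Φ(0.195) ≈ 0.577
(confirmed by simulation), not the upper-tail mass beyond µ + σ (≈ 0.159)
that one might expect from the "mean + 1 sd" phrasing. The ≥50%-of-
replicates rule reduces, but cannot eliminate, substrate-level false
positives. Consequently the classifier's planted-truth *sensitivity* is
1.0 at large effect sizes, but its *specificity* is structurally below 1.0
for any bulk with spread. This is a property of the prescribed threshold
procedure (a moment fit deliberately uncorrected for truncation), kept
as specified; the acceptance suite pins the analytic null rate and keeps
a faithful, failing specificity test.

## Validation

The confusion matrix cross-tabulates measured vs predicted binary calls
(rows = experiment, columns = prediction) over the intersection of tested
and simulatable substrates; one-sided substrates are dropped and logged,
never imputed. Agreement is the concordant fraction with nearest-integer
percent. Growth-rate validation fixes each pair's measured uptake rate,
maximizes biomass, and reports the Pearson correlation between measured
and simulated rates (undefined, and refused, for fewer than two pairs or
zero variance).

## FSEOF

Stage one: the theoretical maximum product flux with biomass pinned to 0.
Stage two: for k = 1..n (default n = 10), enforce product flux
≥ (k/n)·f·v_max (default f = 0.9; enforcing the full maximum would pin
growth to zero), maximize biomass, refine with pFBA. A reaction is an
amplification target when its flux keeps a constant sign, |v| is
non-decreasing at every step (ε = 1e-9), and strictly increases overall;
targets are ranked by |v_last|/|v_first| (switch-ons rank first). The
product exchange and its transport chain rise by construction and are
excluded via an explicit exclude list.

## Synthetic generators

All generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; identical seeds give byte-identical artifacts.

The toy reference model is a three-compartment respiration network with a
lactate branch, a low-yield glycolysis bypass, an erythritol uptake stub
without catabolism, and planted dead ends. Currency metabolites use
pseudo-element formulas chosen so every internal reaction is exactly mass-
and charge-balanced. Its growth optimum has the closed form
µ = min(nutrient_cap, (26·uptake − NGAM)/30), and the FSEOF trunk fluxes
under the nutrient cap obey g = (61 + 12L)/26 and x = (35 − L)/13 for
enforced lactate L — these closed forms are the oracles for the LP and
FSEOF tests. The homolog fixture plants an exact (covered, sole-catalyst)
partition (at most 3 covered genes — one per isoenzyme group). The plate
fixture plants positives at a configurable effect size (in bulk-sd units,
default 10) over a Normal(0.05, 0.01) bulk with triplicates. The
growth-rate fixture samples uptake rates and records simulated µ plus
optional Gaussian noise.

## Pipeline

`forge run --config run.yml` executes translate → resolve orphans →
balance audit → draft SBML → plate growth-calling → substrate simulation +
confusion → optional growth-rate validation → optional FSEOF. Substrate
names map to exchange ids only through the explicit config mapping;
unmapped names are dropped and reported. Each run writes structured logs
and a manifest with SHA-256 digests of every artifact; identical inputs
reproduce identical digests. A stage failure aborts with the stage name,
keeping artifacts already written.

## Limitations

- The LP layer targets correctness and reproducibility, not scale: dense
  matrices and per-reaction FVA solves are fine for fixture-sized models
  (tens to hundreds of reactions), not for 2000+-reaction GSMMs.
- Orphan retention is purely structural (flux-carrying vs blocked); no
  literature or sequence evidence is consulted.
- pFBA resolves most but not all degeneracy: exact ties between parallel
  routes of equal total flux may remain; tests therefore assert objective
  values, planted classifications, and closed-form trunk fluxes, not
  arbitrary individual fluxes.
- The phenotype classifier's specificity ceiling discussed above is
  inherent to the prescribed thresholding, not tunable away without
  changing the procedure (e.g. a truncation-corrected fit).
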