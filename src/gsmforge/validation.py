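"""Quantitative model-vs-experiment agreement.

Two complementary checks: a confusion matrix of binary growth calls over
the substrates tested on phenotype plates (rows = experiment, columns =
prediction), and the Pearson correlation between measured and simulated
growth rates at measured substrate uptake rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gsmforge.fba import FbaError, GrowthCallSet, MediumSpec, fba, apply_medium
from gsmforge.model import MetabolicModel


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 growth-call agreement table.

    Cell names read row-then-column with rows = experiment and columns =
    prediction: ``growth_growth`` means the experiment saw growth and the
    model predicted growth.
    """

    growth_growth: int
    growth_no: int
    no_growth: int
    no_no: int

    def __post_init__(self) -> None:
        for v in (self.growth_growth, self.growth_no, self.no_growth, self.no_no):
            if v < 0 or int(v) != v:
                raise ValidationError("confusion counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.growth_growth + self.growth_no + self.no_growth + self.no_no

    def as_dict(self) -> dict[str, int]:
        return {
            "exp_growth_pred_growth": self.growth_growth,
            "exp_growth_pred_no": self.growth_no,
            "exp_no_pred_growth": self.no_growth,
            "exp_no_pred_no": self.no_no,
        }

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix(
            growth_growth=self.growth_growth,
            growth_no=self.no_growth,
            no_growth=self.growth_no,
            no_no=self.no_no,
        )


def confusion(
    measured: GrowthCallSet, predicted: GrowthCallSet
) -> tuple[ConfusionMatrix, list[str]]:
    """Cross-tabulate measured vs predicted calls.

    Substrates present on only one side are dropped (and returned in the
    drop log), never imputed: the comparison universe is the intersection
    of tested and simulatable substrates.
    """
    shared = sorted(set(measured.calls) & set(predicted.calls))
    dropped = sorted(set(measured.calls) ^ set(predicted.calls))
    gg = gn = ng = nn = 0
    for s in shared:
        m, p = measured.calls[s], predicted.calls[s]
        if m and p:
            gg += 1
        elif m and not p:
            gn += 1
        elif not m and p:
            ng += 1
        else:
            nn += 1
    return ConfusionMatrix(gg, gn, ng, nn), dropped


def agreement(matrix: ConfusionMatrix) -> tuple[float, int]:
    """Fraction of concordant calls and its nearest-integer percentage."""
    if matrix.total == 0:
        raise ValidationError("agreement undefined for an empty matrix")
    frac = (matrix.growth_growth + matrix.no_no) / matrix.total
    return frac, round(frac * 100)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("pearson requires two equal-length vectors of n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class GrowthRatePair:
    """A literature-style (uptake rate, growth rate) observation."""

    substrate: str
    uptake_rate: float  # mmol/gDW/h
    growth_rate: float  # 1/h
    source: str = ""

    def __post_init__(self) -> None:
        if self.uptake_rate < 0 or self.growth_rate < 0:
            raise ValidationError("rates must be non-negative")


def growth_rate_validation(
    model: MetabolicModel,
    pairs: list[GrowthRatePair],
    substrate_exchanges: dict[str, str],
    base_medium: MediumSpec,
) -> tuple[dict[int, float], float]:
    """Simulate µ at each pair's measured uptake rate and correlate.

    For each pair the substrate's exchange uptake is fixed to the measured
    rate, biomass is maximized, and the simulated µ recorded; the return
    is (per-pair simulated µ keyed by pair index, Pearson r between
    measured and simulated µ).  Pairs whose substrate has no exchange are
    skipped and absent from the result.
    """
    simulated: dict[int, float] = {}
    measured: list[float] = []
    for i, pair in enumerate(pairs):
        ex = substrate_exchanges.get(pair.substrate)
        if ex is None or ex not in model.reactions:
            continue
        medium = replace(base_medium, carbon_source=ex, uptake_rate=pair.uptake_rate)
        try:
            result = fba(apply_medium(model, medium))
        except FbaError:
            continue
        simulated[i] = result.objective_value if result.ok else 0.0
        measured.append(pair.growth_rate)
    if len(simulated) < 2:
        raise ValidationError(
            "pearson correlation requires at least two simulatable pairs"
        )
    r = pearson(measured, list(simulated.values()))
    return simulated, r


# ---------------------------------------------------------------------
# pairs CSV I/O
# ---------------------------------------------------------------------

def read_pairs_csv(path: str) -> list[GrowthRatePair]:
    df = pd.read_csv(path)
    required = ["substrate", "uptake_rate", "growth_rate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"pairs CSV lacks columns: {missing}")
    return [
        GrowthRatePair(
            substrate=str(row.substrate),
            uptake_rate=float(row.uptake_rate),
            growth_rate=float(row.growth_rate),
            source=str(getattr(row, "source", "")),
        )
        for row in df.itertuples(index=False)
    ]


def write_pairs_csv(pairs: list[GrowthRatePair], path: str) -> None:
    pd.DataFrame(
        [
            {
                "substrate": p.substrate,
                "uptake_rate": p.uptake_rate,
                "growth_rate": p.growth_rate,
                "source": p.source,
            }
            for p in pairs
        ]
    ).to_csv(path, index=False, float_format="%.8f")
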