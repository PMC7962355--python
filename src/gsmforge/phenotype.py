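"""Phenotype-microarray growth calling.

Each well of a phenotype plate holds a different sole carbon source;
respiration reduces a tetrazolium dye, read as optical density at 490 nm
(750 nm tracks biomass and is carried through I/O but not used by the
classifier).  Per plate, the distribution of OD increases is a low-ΔOD
normal bulk plus a high-ΔOD tail of clearly respiring substrates.  The
growth call works per plate: values strictly above the plate's arithmetic
mean are removed, a normal distribution is fitted to the remainder by
moment matching, and the cutoff is the fitted mean plus one fitted
standard deviation.  A substrate is called metabolized when at least 50%
of replicate plates put its well strictly above their own cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from gsmforge.fba import GrowthCallSet

DYE_WAVELENGTH = 490
BIOMASS_WAVELENGTH = 750


class PlateError(ValueError):
    """Malformed plate data or degenerate threshold input."""


@dataclass(frozen=True)
class WellReading:
    substrate: str
    od_t0: float
    od_tend: float

    def __post_init__(self) -> None:
        if self.od_t0 < 0 or self.od_tend < 0:
            raise PlateError(f"negative OD for substrate {self.substrate!r}")


@dataclass
class PmPlate:
    """One physical plate at one replicate index.

    ``wells`` maps well id → {wavelength → reading}; every well must carry
    the dye wavelength at both timepoints.
    """

    plate_id: str
    replicate: int
    wells: dict[str, dict[int, WellReading]]

    def substrate_of(self, well: str) -> str:
        readings = self.wells[well]
        return next(iter(readings.values())).substrate

    def layout(self) -> dict[str, str]:
        return {w: self.substrate_of(w) for w in self.wells}


@dataclass(frozen=True)
class PlateThreshold:
    """The per-plate growth cutoff.

    ``truncation_mean`` is the arithmetic mean of all ΔOD on the plate
    (the single truncation point); ``mean``/``sd`` are the sample moments
    (n−1 denominator) of the retained values; ``cutoff = mean + sd``.
    """

    truncation_mean: float
    mean: float
    sd: float
    n_retained: int

    @property
    def cutoff(self) -> float:
        return self.mean + self.sd


def od_increase(plate: PmPlate, wavelength: int = DYE_WAVELENGTH) -> dict[str, float]:
    """ΔOD = OD(t_end) − OD(t0) per well; negative drifts are kept as-is."""
    deltas: dict[str, float] = {}
    for well, readings in plate.wells.items():
        if wavelength not in readings:
            raise PlateError(
                f"well {well!r} on plate {plate.plate_id!r} lacks a reading "
                f"at {wavelength} nm"
            )
        r = readings[wavelength]
        deltas[well] = r.od_tend - r.od_t0
    return deltas


def plate_threshold(deltas) -> PlateThreshold:
    """Derive the growth cutoff from one plate's ΔOD values.

    One truncation pass: values strictly above the plate mean (the
    positive tail) are removed; the retained bulk is summarized by its
    sample mean and sample standard deviation, and the cutoff is one
    standard deviation above that mean.
    """
    values = [float(v) for v in deltas]
    if len(values) < 2:
        raise PlateError("plate threshold requires at least 2 values")
    # fsum keeps the mean of identical values exactly equal to them,
    # so the ``v <= mean`` truncation below is not broken by summation
    # round-off
    overall_mean = math.fsum(values) / len(values)
    retained = [v for v in values if v <= overall_mean]
    if len(retained) < 2:
        raise PlateError(
            "degenerate distribution: fewer than 2 values at or below the "
            "plate mean"
        )
    mean = math.fsum(retained) / len(retained)
    var = sum((v - mean) ** 2 for v in retained) / (len(retained) - 1)
    return PlateThreshold(
        truncation_mean=overall_mean,
        mean=mean,
        sd=math.sqrt(var),
        n_retained=len(retained),
    )


def _check_layouts(plates: list[PmPlate]) -> dict[str, str]:
    layout = plates[0].layout()
    for plate in plates[1:]:
        other = plate.layout()
        bad = sorted(
            w
            for w in set(layout) | set(other)
            if layout.get(w) != other.get(w)
        )
        if bad:
            raise PlateError(
                f"replicate plates disagree on layout at wells {bad} "
                f"({plates[0].plate_id!r} vs {plate.plate_id!r})"
            )
    return layout


def call_growth(
    plates: list[PmPlate],
    exclude: frozenset[str] | set[str] = frozenset(),
    wavelength: int = DYE_WAVELENGTH,
) -> GrowthCallSet:
    """Call metabolized substrates from replicate plates.

    Each replicate plate gets its own threshold (plate effects differ);
    a well is positive on a plate iff its ΔOD strictly exceeds that
    plate's cutoff, and a substrate is metabolized iff the positive
    replicate fraction is ≥ 0.5.  ``exclude`` names substrates with known
    abiotic dye reduction, removed before thresholding and never called.
    """
    if not plates:
        raise PlateError("no plates supplied")
    layout = _check_layouts(plates)
    wells = [w for w in layout if layout[w] not in exclude]
    positives: dict[str, int] = {layout[w]: 0 for w in wells}
    for plate in plates:
        deltas = od_increase(plate, wavelength)
        threshold = plate_threshold([deltas[w] for w in wells])
        for w in wells:
            if deltas[w] > threshold.cutoff:
                positives[layout[w]] += 1
    n = len(plates)
    calls = {s: positives[s] / n >= 0.5 for s in positives}
    return GrowthCallSet(
        calls=calls,
        provenance="measured",
        threshold=0.5,
        values={s: positives[s] / n for s in positives},
    )


def replicate_thresholds(
    plates: list[PmPlate],
    exclude: frozenset[str] | set[str] = frozenset(),
    wavelength: int = DYE_WAVELENGTH,
) -> dict[str, PlateThreshold]:
    """Per-plate thresholds, for the threshold log written next to calls."""
    layout = _check_layouts(plates)
    wells = [w for w in layout if layout[w] not in exclude]
    out: dict[str, PlateThreshold] = {}
    for plate in plates:
        deltas = od_increase(plate, wavelength)
        out[f"{plate.plate_id}:{plate.replicate}"] = plate_threshold(
            [deltas[w] for w in wells]
        )
    return out


# ---------------------------------------------------------------------
# plate CSV I/O
# ---------------------------------------------------------------------

_COLUMNS = ["plate_id", "replicate", "well", "substrate", "wavelength_nm", "od_t0", "od_tend"]


def plates_to_frame(plates: list[PmPlate]) -> pd.DataFrame:
    rows = []
    for plate in plates:
        for well in sorted(plate.wells):
            for wl in sorted(plate.wells[well]):
                r = plate.wells[well][wl]
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "replicate": plate.replicate,
                        "well": well,
                        "substrate": r.substrate,
                        "wavelength_nm": wl,
                        "od_t0": r.od_t0,
                        "od_tend": r.od_tend,
                    }
                )
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_plates_csv(plates: list[PmPlate], path: str) -> None:
    plates_to_frame(plates).to_csv(path, index=False, float_format="%.6f")


def read_plates_csv(path: str) -> list[PmPlate]:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"plate CSV lacks columns: {missing}")
    plates: dict[tuple[str, int], PmPlate] = {}
    for row in df.itertuples(index=False):
        key = (str(row.plate_id), int(row.replicate))
        plate = plates.setdefault(
            key, PmPlate(plate_id=key[0], replicate=key[1], wells={})
        )
        plate.wells.setdefault(str(row.well), {})[int(row.wavelength_nm)] = WellReading(
            substrate=str(row.substrate),
            od_t0=float(row.od_t0),
            od_tend=float(row.od_tend),
        )
    return [plates[k] for k in sorted(plates)]
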