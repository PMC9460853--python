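"""Chemotype scoring of fennel plants from gas-chromatography peak areas.

Wild fennel (*Foeniculum vulgare*) essential oil is dominated by two
phenylpropanoids, *trans*-anethole and estragole, whose peak-area ratio is
treated as a per-plant allele-frequency readout at a putative multicopy
phenylpropanoid-biosynthesis locus:

* ``erc`` — estragole relative content, estragole area / (estragole +
  anethole areas);
* ``arc`` — *trans*-anethole relative content, ``1 - erc``.

Fenchone, a terpene marker of bitter fennel, is scored codominantly at a
putative single-copy locus from its share of the integrated essential-oil
peak area: score 0 when fenchone is absent, 2 when it exceeds the 15 %
threshold, 1 otherwise.  Population allele frequencies pool these per-plant
values: ``fp`` (fenchone presence) is the score sum over 2N haploid genomes,
and ``erc``/``arc`` population frequencies are arithmetic means of per-plant
values.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FENCHONE_THRESHOLD",
    "ChemotypeError",
    "UndefinedRatioError",
    "GCPeakRecord",
    "PlantChemotype",
    "ChemicalPopulationSummary",
    "GenotypeGroupProportions",
    "compute_relative_contents",
    "score_fenchone",
    "pool_population",
    "classify_genotype_groups",
    "read_peak_table",
    "write_population_summary",
    "summaries_to_frame",
]

#: Fenchone % of essential-oil peak area separating putative single-allele
#: (score 1) from two-allele (score 2) plants.
FENCHONE_THRESHOLD = 15.0

PEAK_TABLE_COLUMNS = (
    "plant_id",
    "population_id",
    "area_anethole",
    "area_estragole",
    "area_fenchone",
)


class ChemotypeError(ValueError):
    """Invalid chemotype input."""


class UndefinedRatioError(ChemotypeError):
    """Both phenylpropanoid peak areas are zero; erc/arc is undefined."""


@dataclass(frozen=True)
class GCPeakRecord:
    """One plant's integrated GC peak areas (arbitrary area units)."""

    plant_id: str
    population_id: str
    area_anethole: float
    area_estragole: float
    area_fenchone: float

    def __post_init__(self) -> None:
        for name in ("area_anethole", "area_estragole", "area_fenchone"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ChemotypeError(
                    f"plant {self.plant_id!r}: {name} must be finite and >= 0, got {value!r}"
                )
        if self.area_anethole + self.area_estragole <= 0:
            raise UndefinedRatioError(
                f"plant {self.plant_id!r}: both phenylpropanoid areas are zero; "
                "erc/arc undefined"
            )

    @property
    def total_area(self) -> float:
        return self.area_anethole + self.area_estragole + self.area_fenchone


@dataclass(frozen=True)
class PlantChemotype:
    """Derived per-plant chemotype: erc/arc plus the fenchone allele score."""

    plant_id: str
    population_id: str
    erc: float
    fenchone_pct: float
    fenchone_score: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.erc <= 1.0:
            raise ChemotypeError(f"plant {self.plant_id!r}: erc {self.erc} not in [0, 1]")
        if not 0.0 <= self.fenchone_pct <= 100.0:
            raise ChemotypeError(
                f"plant {self.plant_id!r}: fenchone_pct {self.fenchone_pct} not in [0, 100]"
            )
        if self.fenchone_score not in (0, 1, 2):
            raise ChemotypeError(
                f"plant {self.plant_id!r}: fenchone_score must be 0, 1 or 2"
            )
        if (self.fenchone_score == 0) != (self.fenchone_pct == 0.0):
            raise ChemotypeError(
                f"plant {self.plant_id!r}: score 0 iff fenchone_pct is exactly 0"
            )

    @property
    def arc(self) -> float:
        """*trans*-anethole relative content, exactly ``1 - erc``."""
        return 1.0 - self.erc


@dataclass(frozen=True)
class ChemicalPopulationSummary:
    """Pooled chemical allele frequencies for one population.

    ``stats`` carries max / mean / min / sd rows for each of fp, fa, erc and
    arc, computed over per-plant values (per-plant fp is score/2).  SDs use
    the sample (n-1) convention.
    """

    population_id: str
    n_plants: int
    fp: float
    erc_mean: float
    stats: pd.DataFrame = field(repr=False)

    @property
    def fa(self) -> float:
        return 1.0 - self.fp

    @property
    def arc_mean(self) -> float:
        return 1.0 - self.erc_mean


@dataclass(frozen=True)
class GenotypeGroupProportions:
    """Proportions of the three putative fenchone genotype groups."""

    prop_fa_homozygote: float
    prop_heterozygote: float
    prop_fp_homozygote: float

    def __post_init__(self) -> None:
        total = self.prop_fa_homozygote + self.prop_heterozygote + self.prop_fp_homozygote
        if abs(total - 1.0) > 1e-9:
            raise ChemotypeError(f"genotype-group proportions sum to {total}, not 1")

    @property
    def fenchone_containing(self) -> float:
        """Fraction of plants with at least one fenchone allele (score >= 1)."""
        return self.prop_heterozygote + self.prop_fp_homozygote

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.prop_fa_homozygote, self.prop_heterozygote, self.prop_fp_homozygote)


def score_fenchone(fenchone_pct: float, threshold: float = FENCHONE_THRESHOLD) -> int:
    """Score fenchone allele dosage from its % of essential-oil peak area.

    0: no fenchone detected; 2: above ``threshold``; 1 otherwise.  A value
    exactly at the threshold is scored 1 (conservative toward heterozygote;
    the published criterion leaves the boundary open).
    """
    if not math.isfinite(fenchone_pct) or not 0.0 <= fenchone_pct <= 100.0:
        raise ChemotypeError(f"fenchone_pct {fenchone_pct!r} not in [0, 100]")
    if fenchone_pct == 0.0:
        return 0
    if fenchone_pct > threshold:
        return 2
    return 1


def compute_relative_contents(
    record: GCPeakRecord, threshold: float = FENCHONE_THRESHOLD
) -> PlantChemotype:
    """Derive a :class:`PlantChemotype` from one plant's peak areas.

    erc = estragole / (estragole + anethole); fenchone % is taken relative to
    the total integrated area of the three recorded peaks.
    """
    phenylpropanoid = record.area_anethole + record.area_estragole
    erc = record.area_estragole / phenylpropanoid
    fenchone_pct = 100.0 * record.area_fenchone / record.total_area
    return PlantChemotype(
        plant_id=record.plant_id,
        population_id=record.population_id,
        erc=erc,
        fenchone_pct=fenchone_pct,
        fenchone_score=score_fenchone(fenchone_pct, threshold=threshold),
    )


def _stat_row(values: np.ndarray) -> dict[str, float]:
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "max": float(values.max()),
        "mean": float(values.mean()),
        "min": float(values.min()),
        "sd": sd,
    }


def pool_population(chemotypes: Sequence[PlantChemotype]) -> ChemicalPopulationSummary:
    """Pool per-plant chemotypes into population allele frequencies.

    fp is the score sum divided by the number of haploid genomes (2N); the
    erc population frequency is the arithmetic mean of per-plant erc.
    """
    if len(chemotypes) == 0:
        raise ChemotypeError("cannot pool an empty population")
    populations = {c.population_id for c in chemotypes}
    if len(populations) != 1:
        raise ChemotypeError(f"mixed population ids in pool: {sorted(populations)}")
    (population_id,) = populations

    scores = np.array([c.fenchone_score for c in chemotypes], dtype=float)
    erc = np.array([c.erc for c in chemotypes], dtype=float)
    per_plant = {"fp": scores / 2.0, "fa": 1.0 - scores / 2.0, "erc": erc, "arc": 1.0 - erc}
    stats = pd.DataFrame({name: _stat_row(vals) for name, vals in per_plant.items()}).T
    stats = stats[["max", "mean", "min", "sd"]]

    return ChemicalPopulationSummary(
        population_id=population_id,
        n_plants=len(chemotypes),
        fp=float(scores.sum() / (2.0 * len(chemotypes))),
        erc_mean=float(erc.mean()),
        stats=stats,
    )


def classify_genotype_groups(
    chemotypes: Sequence[PlantChemotype],
) -> GenotypeGroupProportions:
    """Proportions of score-0 / score-1 / score-2 plants."""
    if len(chemotypes) == 0:
        raise ChemotypeError("cannot classify an empty plant set")
    scores = np.array([c.fenchone_score for c in chemotypes])
    n = scores.size
    return GenotypeGroupProportions(
        prop_fa_homozygote=float((scores == 0).sum() / n),
        prop_heterozygote=float((scores == 1).sum() / n),
        prop_fp_homozygote=float((scores == 2).sum() / n),
    )


def read_peak_table(path) -> list[GCPeakRecord]:
    """Read a delimited (CSV/TSV) per-plant GC peak table.

    Expected header: ``plant_id,population_id,area_anethole,area_estragole,
    area_fenchone``.  Plants with zero total phenylpropanoid area are rejected
    here rather than silently dropped.
    """
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = set(PEAK_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ChemotypeError(f"peak table missing columns: {sorted(missing)}")
    return [
        GCPeakRecord(
            plant_id=str(row.plant_id),
            population_id=str(row.population_id),
            area_anethole=float(row.area_anethole),
            area_estragole=float(row.area_estragole),
            area_fenchone=float(row.area_fenchone),
        )
        for row in frame.itertuples(index=False)
    ]


def summaries_to_frame(
    summaries: Iterable[ChemicalPopulationSummary],
) -> pd.DataFrame:
    """Long-format population summary: one row per population and field."""
    rows = []
    for s in summaries:
        for name in ("fp", "fa", "erc", "arc"):
            r = s.stats.loc[name]
            rows.append(
                {
                    "population_id": s.population_id,
                    "n_plants": s.n_plants,
                    "field": name,
                    "max": r["max"],
                    "average": r["mean"],
                    "min": r["min"],
                    "sd": r["sd"],
                }
            )
    return pd.DataFrame(rows)


def write_population_summary(
    summaries: Iterable[ChemicalPopulationSummary], path
) -> None:
    """Write a population summary CSV with max/average/min columns and SD."""
    summaries_to_frame(summaries).to_csv(path, index=False)
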