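"""PCR-RFLP gel densitometry: band detection, ladder sizing, ITS allele fractions.

The nrDNA ITS amplicon of fennel (~684 bp) digested with MspI separates into
three diagnostic electrophoretic bands whose relative densitometric areas are
read as allele frequencies of the multicopy ITS locus:

* 684 bp — undigested amplicon, allele ``itsA`` (no MspI site);
* 529 bp — allele ``itsB`` (one site; companion fragment 153 bp);
* 344 bp — allele ``itsC`` (two sites; companions 185 bp and 153 bp).

Only the 684/529/344 bands enter the allele-fraction denominator; the small
153/185 bp fragments are used for structural pattern validation only.  Lanes
are sized against a 100 bp ladder by piecewise-linear interpolation of
log(size) versus migration.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "DIAGNOSTIC_SIZES",
    "QUANTITATION_SIZES",
    "MSPI_SITE",
    "MSPI_CUT_OFFSET",
    "DensitometryError",
    "CalibrationError",
    "AmbiguousBandError",
    "Band",
    "GelLane",
    "LadderCalibration",
    "SizeEstimate",
    "ITSProfile",
    "MatchResult",
    "PatternReport",
    "detect_bands",
    "calibrate_ladder",
    "match_diagnostic_bands",
    "its_allele_fractions",
    "profile_from_match",
    "digest_sequence",
    "validate_pattern",
    "replicate_reproducibility",
    "read_band_table",
    "read_trace_table",
    "read_fasta",
    "write_profiles",
]

#: MspI diagnostic fragment sizes (bp) of the fennel ITS amplicon.
DIAGNOSTIC_SIZES = (684, 529, 344, 185, 153)
#: Bands entering the allele-fraction denominator (itsA, itsB, itsC).
QUANTITATION_SIZES = (684, 529, 344)

MSPI_SITE = "CCGG"
MSPI_CUT_OFFSET = 1  # MspI cuts C^CGG


class DensitometryError(ValueError):
    """Invalid densitometry input."""


class CalibrationError(DensitometryError):
    """Ladder anchors are inconsistent."""


class AmbiguousBandError(DensitometryError):
    """Two detected bands compete for one diagnostic size."""


@dataclass(frozen=True)
class Band:
    """One electrophoretic band: migration distance, integrated area, size."""

    migration: float
    area: float
    size_bp: float | None = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.migration) or self.migration <= 0:
            raise DensitometryError(f"band migration must be > 0, got {self.migration!r}")
        if not math.isfinite(self.area) or self.area < 0:
            raise DensitometryError(f"band area must be >= 0, got {self.area!r}")


@dataclass
class GelLane:
    """One gel lane; bands are kept sorted by migration distance."""

    lane_id: str
    bands: list[Band]
    plant_id: str | None = None
    is_ladder: bool = False

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: b.migration)


@dataclass(frozen=True)
class SizeEstimate:
    size_bp: float
    extrapolated: bool


@dataclass(frozen=True)
class LadderCalibration:
    """Piecewise-linear map of migration to log(fragment size).

    Exact at the ladder anchors; queries outside the anchor range are
    linearly extrapolated on the end segments and flagged.
    """

    migrations: np.ndarray
    sizes: np.ndarray
    log_sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        migrations = np.asarray(self.migrations, dtype=float)
        sizes = np.asarray(self.sizes, dtype=float)
        if migrations.size != sizes.size or migrations.size < 2:
            raise CalibrationError("need at least two (migration, size) anchors")
        for k in range(1, migrations.size):
            if migrations[k] <= migrations[k - 1]:
                raise CalibrationError(
                    f"anchor migrations not strictly increasing at anchor {k} "
                    f"(migration {migrations[k]})"
                )
            if sizes[k] >= sizes[k - 1]:
                raise CalibrationError(
                    f"anchor sizes not strictly decreasing at anchor {k} "
                    f"(size {sizes[k]})"
                )
        object.__setattr__(self, "migrations", migrations)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "log_sizes", np.log(sizes))

    def size_at(self, migration: float) -> SizeEstimate:
        """Fragment size (bp) at a migration distance."""
        m = self.migrations
        extrapolated = migration < m[0] or migration > m[-1]
        if extrapolated:
            # continue the end segment's slope
            seg = slice(0, 2) if migration < m[0] else slice(-2, None)
            slope = np.diff(self.log_sizes[seg])[0] / np.diff(m[seg])[0]
            anchor = 0 if migration < m[0] else -1
            log_size = self.log_sizes[anchor] + slope * (migration - m[anchor])
        else:
            log_size = float(np.interp(migration, m, self.log_sizes))
        return SizeEstimate(size_bp=float(np.exp(log_size)), extrapolated=extrapolated)

    def migration_for(self, size_bp: float) -> float:
        """Inverse query: migration at which a fragment of this size runs."""
        # log_sizes decrease with migration; interp needs ascending x
        return float(np.interp(math.log(size_bp), self.log_sizes[::-1], self.migrations[::-1]))


@dataclass(frozen=True)
class ITSProfile:
    """Normalized ITS allele fractions of one plant; itsA + itsB + itsC = 1."""

    plant_id: str
    itsA: float
    itsB: float
    itsC: float

    def __post_init__(self) -> None:
        for name in ("itsA", "itsB", "itsC"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0 or v > 1:
                raise DensitometryError(f"{name}={v!r} not in [0, 1]")
        if abs(self.itsA + self.itsB + self.itsC - 1.0) > 1e-9:
            raise DensitometryError("ITS fractions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.itsA, self.itsB, self.itsC])


@dataclass(frozen=True)
class MatchResult:
    """Diagnostic-band assignment for one lane."""

    assigned: dict[int, Band | None]
    unassigned: list[Band]

    def area(self, size: int) -> float:
        band = self.assigned.get(size)
        return band.area if band is not None else 0.0


@dataclass(frozen=True)
class PatternReport:
    """Structural-consistency report for a matched restriction pattern."""

    warnings: tuple[str, ...]

    @property
    def consistent(self) -> bool:
        return not self.warnings


def detect_bands(
    trace,
    positions=None,
    baseline_quantile: float = 0.05,
    min_prominence: float | None = None,
) -> list[Band]:
    """Detect bands in a 1-D lane intensity trace.

    The baseline is the ``baseline_quantile`` intensity quantile.  Local
    maxima whose prominence exceeds ``min_prominence`` (default: 5 % of the
    above-baseline dynamic range) become bands; each band's area integrates
    the above-baseline signal between the minima separating it from its
    neighbours.  A flat trace yields an empty list.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size < 3:
        raise DensitometryError("trace must be 1-D with at least 3 samples")
    if np.any(trace < 0) or not np.all(np.isfinite(trace)):
        raise DensitometryError("trace intensities must be finite and non-negative")
    if positions is None:
        positions = np.arange(trace.size, dtype=float)
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != trace.shape:
            raise DensitometryError("positions and trace must have the same length")

    baseline = float(np.quantile(trace, baseline_quantile))
    work = np.clip(trace - baseline, 0.0, None)
    if work.max() == 0.0:
        return []
    prominence = min_prominence if min_prominence is not None else 0.05 * work.max()
    peaks, _ = find_peaks(work, prominence=prominence)
    if peaks.size == 0:
        return []

    # partition the trace at the minima between consecutive peaks so band
    # areas sum to the total above-baseline signal
    edges = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        edges.append(left + int(np.argmin(work[left : right + 1])))
    edges.append(trace.size - 1)

    bands = []
    for k, peak in enumerate(peaks):
        lo, hi = edges[k], edges[k + 1]
        area = float(np.trapezoid(work[lo : hi + 1], positions[lo : hi + 1]))
        bands.append(Band(migration=float(positions[peak]), area=area))
    return bands


def calibrate_ladder(ladder: GelLane, known_sizes: Sequence[float]) -> LadderCalibration:
    """Fit the ladder-lane calibration from known fragment sizes.

    ``known_sizes`` pair with the ladder bands in migration order, so they
    must be strictly decreasing (largest fragment migrates least); any other
    ordering indicates a mislabeled ladder and is an error.
    """
    if len(ladder.bands) != len(known_sizes):
        raise CalibrationError(
            f"ladder has {len(ladder.bands)} bands but {len(known_sizes)} known sizes"
        )
    sizes = [float(s) for s in known_sizes]
    for k in range(1, len(sizes)):
        if sizes[k] >= sizes[k - 1]:
            raise CalibrationError(
                f"ladder sizes not strictly decreasing at anchor {k} ({sizes[k]} bp)"
            )
    return LadderCalibration(
        migrations=np.array([b.migration for b in ladder.bands]),
        sizes=np.array(sizes),
    )


def match_diagnostic_bands(
    lane: GelLane,
    calibration: LadderCalibration,
    tolerance_frac: float = 0.05,
    diagnostic_sizes: Sequence[int] = DIAGNOSTIC_SIZES,
) -> MatchResult:
    """Assign each detected band to its nearest diagnostic fragment size.

    A band is assigned when its estimated size is within ``tolerance_frac``
    (relative) of a diagnostic size; two bands competing for one size raise
    :class:`AmbiguousBandError`.  Bands matching no diagnostic size are
    reported as unassigned.
    """
    assigned: dict[int, Band | None] = {int(s): None for s in diagnostic_sizes}
    unassigned: list[Band] = []
    for band in lane.bands:
        estimate = calibration.size_at(band.migration)
        sized = replace(band, size_bp=estimate.size_bp, extrapolated=estimate.extrapolated)
        best = min(diagnostic_sizes, key=lambda s: abs(estimate.size_bp - s) / s)
        if abs(estimate.size_bp - best) / best <= tolerance_frac:
            if assigned[int(best)] is not None:
                raise AmbiguousBandError(
                    f"lane {lane.lane_id!r}: bands at migrations "
                    f"{assigned[int(best)].migration} and {sized.migration} both "
                    f"match the {best} bp diagnostic size"
                )
            assigned[int(best)] = sized
        else:
            unassigned.append(sized)
    return MatchResult(assigned=assigned, unassigned=unassigned)


def its_allele_fractions(
    area_684: float, area_529: float, area_344: float, plant_id: str = ""
) -> ITSProfile:
    """Normalize the three quantitation band areas into ITS allele fractions.

    The 153/185 bp companion fragments are excluded from the denominator.
    """
    areas = np.array([area_684, area_529, area_344], dtype=float)
    if np.any(areas < 0) or not np.all(np.isfinite(areas)):
        raise DensitometryError("band areas must be finite and non-negative")
    total = areas.sum()
    if total <= 0:
        raise DensitometryError("all three quantitation band areas are zero")
    fractions = areas / total
    return ITSProfile(plant_id=plant_id, itsA=fractions[0], itsB=fractions[1], itsC=fractions[2])


def profile_from_match(match: MatchResult, plant_id: str = "") -> ITSProfile:
    """ITS allele fractions from a diagnostic-band match (absent band = 0 area)."""
    return its_allele_fractions(
        match.area(684), match.area(529), match.area(344), plant_id=plant_id
    )


def digest_sequence(
    seq: str, site: str = MSPI_SITE, cut_offset: int = MSPI_CUT_OFFSET
) -> list[int]:
    """In-silico restriction digest: fragment lengths from cutting at every site.

    Every occurrence of ``site`` (overlaps allowed, scanned left to right) is
    cut at ``position + cut_offset``.  Fragment lengths sum to ``len(seq)``;
    a sequence without the site returns one full-length fragment.
    """
    if not seq:
        raise DensitometryError("empty sequence")
    seq = seq.upper()
    site = site.upper()
    if set(seq) - set("ACGT"):
        raise DensitometryError(f"invalid characters in sequence: {sorted(set(seq) - set('ACGT'))}")
    if not site or set(site) - set("ACGT"):
        raise DensitometryError("recognition site must be a non-empty A/C/G/T string")
    if not 0 <= cut_offset <= len(site):
        raise DensitometryError("cut_offset must lie within the recognition site")

    cuts = []
    start = seq.find(site)
    while start != -1:
        pos = start + cut_offset
        if 0 < pos < len(seq):
            cuts.append(pos)
        start = seq.find(site, start + 1)
    cuts = sorted(set(cuts))
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


def _present_sizes(pattern) -> dict[int, float]:
    """Nominal diagnostic size -> measured size for the bands present."""
    if isinstance(pattern, MatchResult):
        return {
            s: (b.size_bp if b.size_bp is not None else float(s))
            for s, b in pattern.assigned.items()
            if b is not None
        }
    if isinstance(pattern, Mapping):
        out = {}
        for s, v in pattern.items():
            if v is None:
                continue
            out[int(s)] = v.size_bp if isinstance(v, Band) and v.size_bp is not None else float(s)
        return out
    return {int(round(s)): float(s) for s in pattern}


def validate_pattern(pattern, slack_bp: float = 5.0) -> PatternReport:
    """Check structural consistency of a matched MspI restriction pattern.

    Rules (report-only, never corrected): a 344 bp band implies a 185 bp
    companion; 344 + 185 should reconstruct the 529 bp parent; 529 + 153
    should reconstruct the 684 bp amplicon, all within ``slack_bp``.
    """
    present = _present_sizes(pattern)
    warnings: list[str] = []
    if 344 in present and 185 not in present:
        warnings.append("344 bp band present without its 185 bp companion fragment")
    if 344 in present and 185 in present:
        total = present[344] + present[185]
        parent = present.get(529, 529.0)
        if abs(total - parent) > slack_bp:
            warnings.append(
                f"secondary fragments sum to {total:.0f} bp, expected ~{parent:.0f} bp"
            )
    if 529 in present and 153 in present:
        total = present[529] + present[153]
        parent = present.get(684, 684.0)
        if abs(total - parent) > slack_bp:
            warnings.append(
                f"primary fragments sum to {total:.0f} bp, expected ~{parent:.0f} bp"
            )
    return PatternReport(warnings=tuple(warnings))


def replicate_reproducibility(
    replicates: Mapping[str, Sequence[ITSProfile]],
) -> pd.DataFrame:
    """Per-sample mean and sample SD of replicate band percentages.

    Returns a long-format table (sample, band, mean_pct, sd_pct) on the %
    scale, mirroring a replicate-reproducibility summary.
    """
    rows = []
    for sample, profiles in replicates.items():
        if len(profiles) < 2:
            raise DensitometryError(
                f"sample {sample!r}: need >= 2 replicates for an SD (got {len(profiles)})"
            )
        values = 100.0 * np.array([p.as_array() for p in profiles])
        for k, band in enumerate(("itsA", "itsB", "itsC")):
            rows.append(
                {
                    "sample": sample,
                    "band": band,
                    "mean_pct": float(values[:, k].mean()),
                    "sd_pct": float(values[:, k].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def read_band_table(path) -> list[GelLane]:
    """Read a band table CSV: lane_id, plant_id, migration, area[, is_ladder]."""
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"lane_id", "migration", "area"}
    missing = required - set(frame.columns)
    if missing:
        raise DensitometryError(f"band table missing columns: {sorted(missing)}")
    lanes = []
    for lane_id, group in frame.groupby("lane_id", sort=False):
        plant = None
        if "plant_id" in group.columns:
            vals = group["plant_id"].dropna().unique()
            plant = str(vals[0]) if len(vals) else None
        is_ladder = bool(group["is_ladder"].iloc[0]) if "is_ladder" in group.columns else False
        bands = [
            Band(migration=float(r.migration), area=float(r.area))
            for r in group.itertuples(index=False)
        ]
        lanes.append(GelLane(lane_id=str(lane_id), bands=bands, plant_id=plant, is_ladder=is_ladder))
    return lanes


def read_trace_table(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read lane traces CSV (lane_id, position, intensity) into arrays per lane."""
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = {"lane_id", "position", "intensity"} - set(frame.columns)
    if missing:
        raise DensitometryError(f"trace table missing columns: {sorted(missing)}")
    out = {}
    for lane_id, group in frame.groupby("lane_id", sort=False):
        group = group.sort_values("position")
        out[str(lane_id)] = (
            group["position"].to_numpy(dtype=float),
            group["intensity"].to_numpy(dtype=float),
        )
    return out


def read_fasta(path) -> dict[str, str]:
    """Read sequences for in-silico digestion from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_profiles(profiles: Iterable[ITSProfile], path) -> None:
    """Write ITS profiles to CSV (plant_id, itsA, itsB, itsC)."""
    pd.DataFrame(
        [
            {"plant_id": p.plant_id, "itsA": p.itsA, "itsB": p.itsB, "itsC": p.itsC}
            for p in profiles
        ]
    ).to_csv(path, index=False)
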