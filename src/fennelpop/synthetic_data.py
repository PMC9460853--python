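"""Synthetic per-plant datasets with the statistical structure of the field study.

Generates GC peak tables, ITS band profiles, and gel lanes (band tables and
1-D traces) for arbitrary population specifications, together with the exact
per-plant and per-population ground truth, so every pipeline stage can be
exercised and validated without field data.

The generative model per plant:

* the fenchone genotype (score 0/1/2) is drawn from explicit per-population
  group proportions (observed cohorts deviate from Hardy-Weinberg, so the
  proportions are free parameters, not derived from fp);
* the fenchone percentage is 0 for score-0 plants, Uniform(1, 15) for
  score-1 and Uniform(15.0001, 60) for score-2, so threshold scoring inverts
  the genotype exactly;
* per-plant erc follows a Beta distribution reparameterized by mean and SD;
* per-plant ITS fractions follow a Dirichlet around the population target
  (two-component when the itsC target is 0, which then stays exactly 0);
* gel band areas are the profile fractions times a total lane intensity with
  lognormal multiplicative noise of a given CV; migrations follow a log-linear
  gel model shared with the companion 100 bp ladder lane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemotypes import GCPeakRecord
from .rflp_densitometry import Band, GelLane, ITSProfile

__all__ = [
    "GEL_MIGRATION_OFFSET",
    "GEL_MIGRATION_SLOPE",
    "GEL_REFERENCE_SIZE",
    "LADDER_SIZES",
    "PopulationSpec",
    "SyntheticStudy",
    "SyntheticDataError",
    "group_props_from_fp",
    "migration_of_size",
    "make_ladder_lane",
    "sample_plant_chemotype",
    "sample_its_profile",
    "synthetic_its_amplicon",
    "render_gel_lane",
    "render_trace",
    "generate_study",
    "default_population_specs",
]


class SyntheticDataError(ValueError):
    """Invalid synthetic-population specification."""


# Log-linear gel geometry: migration = offset + slope * log10(ref / size).
# Arbitrary distance units chosen so the 100-1000 bp ladder spans ~8-48.
GEL_MIGRATION_OFFSET = 5.0
GEL_MIGRATION_SLOPE = 40.0
GEL_REFERENCE_SIZE = 1200.0
LADDER_SIZES = tuple(range(1000, 99, -100))

# Companion small fragments rendered for pattern validation; their areas are
# scaled down (shorter fragments bind less stain) and never quantitated.
_COMPANION_AREA_SCALE = {153: 0.25, 185: 0.30}


def synthetic_its_amplicon(allele: str, rng: np.random.Generator) -> str:
    """A synthetic stand-in sequence for one ITS allelic form.

    The true amplicon sequence is not published, so this constructs a random
    sequence with MspI (CCGG) sites placed to reproduce each allele's
    diagnostic fragment lengths exactly: allele ``A`` has no site (684 bp
    uncut), ``B`` one site (529 + 153 bp), ``C`` two sites (344 + 185 +
    153 bp).  The background alphabet excludes C so no spurious site can
    form.
    """
    def background(n: int) -> str:
        return "".join(rng.choice(list("AGT"), size=n))

    if allele == "A":
        return background(684)
    if allele == "B":
        return background(528) + "CCGG" + background(682 - 532)
    if allele == "C":
        return (
            background(343) + "CCGG" + background(528 - 347) + "CCGG"
            + background(682 - 532)
        )
    raise SyntheticDataError(f"unknown ITS allele {allele!r}; expected A, B or C")


def migration_of_size(size_bp: float) -> float:
    """Migration distance of a fragment under the synthetic gel geometry."""
    return GEL_MIGRATION_OFFSET + GEL_MIGRATION_SLOPE * math.log10(
        GEL_REFERENCE_SIZE / size_bp
    )


def group_props_from_fp(fp: float) -> tuple[float, float, float]:
    """Genotype-group proportions from fp under maximal-heterozygosity allocation.

    Mean score is 2*fp; heterozygotes are maximized, so one homozygote class
    is empty: fp <= 0.5 gives (1-2fp, 2fp, 0), fp > 0.5 gives
    (0, 2(1-fp), 2fp-1).
    """
    if not 0.0 <= fp <= 1.0:
        raise SyntheticDataError(f"fp {fp} not in [0, 1]")
    if fp <= 0.5:
        return (1.0 - 2.0 * fp, 2.0 * fp, 0.0)
    return (0.0, 2.0 * (1.0 - fp), 2.0 * fp - 1.0)


def _beta_params(mean: float, sd: float) -> tuple[float, float] | None:
    """(alpha, beta) for a Beta with the given mean and SD; None = degenerate."""
    if sd <= 0.0 or mean <= 0.0 or mean >= 1.0:
        return None
    max_var = mean * (1.0 - mean)
    var = min(sd * sd, 0.999 * max_var)
    nu = max_var / var - 1.0
    return (mean * nu, (1.0 - mean) * nu)


@dataclass(frozen=True)
class PopulationSpec:
    """Target parameters for one synthetic population.

    ``group_props`` are the (score-0, score-1, score-2) genotype proportions;
    ``erc_mean``/``erc_spread`` the Beta mean and SD of per-plant erc;
    ``its_target`` the mean ITS fractions with Dirichlet concentration
    ``its_concentration``; ``noise_cv_band`` the fractional CV of replicate
    gel band areas.
    """

    population_id: str
    n_plants: int = 17
    group_props: tuple[float, float, float] = (0.085, 0.739, 0.176)
    erc_mean: float = 0.5
    erc_spread: float = 0.2
    its_target: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    its_concentration: float = 50.0
    noise_cv_band: float = 0.04
    total_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_plants < 2:
            raise SyntheticDataError("n_plants must be >= 2")
        if abs(sum(self.group_props) - 1.0) > 1e-9 or min(self.group_props) < 0:
            raise SyntheticDataError("group_props must be non-negative and sum to 1")
        if abs(sum(self.its_target) - 1.0) > 1e-9 or min(self.its_target) < 0:
            raise SyntheticDataError("its_target must be non-negative and sum to 1")
        if not 0.0 <= self.erc_mean <= 1.0:
            raise SyntheticDataError("erc_mean must be in [0, 1]")
        if self.its_concentration <= 0:
            raise SyntheticDataError("its_concentration must be positive")
        if self.noise_cv_band < 0:
            raise SyntheticDataError("noise_cv_band must be >= 0")

    @property
    def fp_true(self) -> float:
        p0, p1, p2 = self.group_props
        return (p1 + 2.0 * p2) / 2.0

    def expected_frequencies(self) -> dict[str, float]:
        """Population frequencies implied by the spec (pooling-formula truth)."""
        return {
            "fp": self.fp_true,
            "fa": 1.0 - self.fp_true,
            "erc": self.erc_mean,
            "arc": 1.0 - self.erc_mean,
            "itsA": self.its_target[0],
            "itsB": self.its_target[1],
            "itsC": self.its_target[2],
        }


def sample_plant_chemotype(
    spec: PopulationSpec, rng: np.random.Generator, plant_id: str | None = None
) -> tuple[GCPeakRecord, dict]:
    """Draw one plant's GC peak record plus its generating truth.

    Peak areas are constructed so that the derived erc equals the drawn value
    exactly and the fenchone percentage (relative to the three-peak total)
    equals the drawn percentage exactly.
    """
    if plant_id is None:
        plant_id = f"{spec.population_id}_p"
    genotype = int(rng.choice(3, p=spec.group_props))
    if genotype == 0:
        fenchone_pct = 0.0
    elif genotype == 1:
        fenchone_pct = float(rng.uniform(1.0, 15.0))
    else:
        fenchone_pct = float(rng.uniform(15.0001, 60.0))

    params = _beta_params(spec.erc_mean, spec.erc_spread)
    erc = spec.erc_mean if params is None else float(rng.beta(*params))
    erc = min(1.0, max(0.0, erc))

    phenylpropanoid_total = float(rng.uniform(50.0, 200.0))
    area_fenchone = phenylpropanoid_total * fenchone_pct / (100.0 - fenchone_pct)
    record = GCPeakRecord(
        plant_id=plant_id,
        population_id=spec.population_id,
        area_anethole=(1.0 - erc) * phenylpropanoid_total,
        area_estragole=erc * phenylpropanoid_total,
        area_fenchone=area_fenchone,
    )
    truth = {"plant_id": plant_id, "genotype_score": genotype, "erc": erc,
             "fenchone_pct": fenchone_pct}
    return record, truth


def sample_its_profile(
    spec: PopulationSpec, rng: np.random.Generator, plant_id: str | None = None
) -> ITSProfile:
    """Draw one plant's true ITS fractions from the population Dirichlet.

    When the itsC target is 0, itsC is exactly 0 for every plant and the
    Dirichlet acts on (itsA, itsB) only.
    """
    if plant_id is None:
        plant_id = f"{spec.population_id}_p"
    a, b, c = spec.its_target
    if c == 0.0:
        alpha = np.array([a, b]) * spec.its_concentration
        fa, fb = rng.dirichlet(alpha)
        fractions = (float(fa), float(fb), 0.0)
    else:
        alpha = np.array([a, b, c]) * spec.its_concentration
        fa, fb, fc = rng.dirichlet(alpha)
        fractions = (float(fa), float(fb), float(fc))
    return ITSProfile(plant_id=plant_id, itsA=fractions[0], itsB=fractions[1],
                      itsC=fractions[2])


def _noise_factor(cv: float, rng: np.random.Generator) -> float:
    """Mean-1 lognormal multiplicative noise with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def make_ladder_lane(lane_id: str = "ladder") -> GelLane:
    """The companion 100 bp ladder lane (100-1000 bp, noiseless migrations)."""
    bands = [Band(migration=migration_of_size(s), area=50.0) for s in LADDER_SIZES]
    return GelLane(lane_id=lane_id, bands=bands, is_ladder=True)


def render_gel_lane(
    profile: ITSProfile,
    total_intensity: float = 1000.0,
    noise_cv_band: float = 0.04,
    rng: np.random.Generator | None = None,
    lane_id: str | None = None,
) -> tuple[GelLane, GelLane]:
    """Render a sample lane (plus its ladder lane) from a true ITS profile.

    Quantitation band areas are fraction x total intensity with lognormal
    noise; the 153 bp (and, when itsC > 0, 185 bp) companion fragments are
    rendered at reduced area.  itsC = 0 produces no 344/185 bands.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if lane_id is None:
        lane_id = f"lane_{profile.plant_id}"
    area_by_size = {684: profile.itsA, 529: profile.itsB}
    if profile.itsC > 0.0:
        area_by_size[344] = profile.itsC
        area_by_size[185] = _COMPANION_AREA_SCALE[185] * profile.itsC
    area_by_size[153] = _COMPANION_AREA_SCALE[153] * (profile.itsB + profile.itsC)

    bands = [
        Band(
            migration=migration_of_size(size),
            area=frac * total_intensity * _noise_factor(noise_cv_band, rng),
        )
        for size, frac in area_by_size.items()
        if frac > 0.0
    ]
    lane = GelLane(lane_id=lane_id, bands=bands, plant_id=profile.plant_id)
    return lane, make_ladder_lane(f"{lane_id}_ladder")


def render_trace(
    lane: GelLane,
    grid_step: float = 0.05,
    sigma: float = 0.35,
    extent: tuple[float, float] = (0.0, 60.0),
) -> tuple[np.ndarray, np.ndarray]:
    """1-D intensity trace of a lane: a Gaussian bump of matching area per band."""
    positions = np.arange(extent[0], extent[1] + grid_step, grid_step)
    intensity = np.zeros_like(positions)
    for band in lane.bands:
        z = (positions - band.migration) / sigma
        intensity += band.area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)
    return positions, intensity


@dataclass
class SyntheticStudy:
    """A generated multi-population study plus its exact ground truth."""

    specs: list[PopulationSpec]
    peak_records: list[GCPeakRecord]
    profiles: list[ITSProfile]
    lanes: list[GelLane] = field(repr=False)
    truth_per_plant: pd.DataFrame = field(repr=False)
    truth_expected: pd.DataFrame = field(repr=False)

    def peak_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plant_id": r.plant_id,
                    "population_id": r.population_id,
                    "area_anethole": r.area_anethole,
                    "area_estragole": r.area_estragole,
                    "area_fenchone": r.area_fenchone,
                }
                for r in self.peak_records
            ]
        )

    def band_table(self) -> pd.DataFrame:
        rows = []
        for lane in self.lanes:
            for band in lane.bands:
                rows.append(
                    {
                        "lane_id": lane.lane_id,
                        "plant_id": lane.plant_id if lane.plant_id else "",
                        "migration": band.migration,
                        "area": band.area,
                        "is_ladder": lane.is_ladder,
                    }
                )
        return pd.DataFrame(rows)

    def trace_table(self, lane_ids=None, **render_kwargs) -> pd.DataFrame:
        frames = []
        for lane in self.lanes:
            if lane_ids is not None and lane.lane_id not in lane_ids:
                continue
            positions, intensity = render_trace(lane, **render_kwargs)
            frames.append(
                pd.DataFrame(
                    {"lane_id": lane.lane_id, "position": positions, "intensity": intensity}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write(self, outdir, include_traces: bool = True) -> None:
        """Write peak table, band table, (optionally) traces, and truth CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peak_table().to_csv(outdir / "peak_table.csv", index=False)
        self.band_table().to_csv(outdir / "band_table.csv", index=False)
        if include_traces:
            self.trace_table().to_csv(outdir / "traces.csv", index=False)
        self.truth_per_plant.to_csv(outdir / "truth_per_plant.csv", index=False)
        self.truth_expected.to_csv(outdir / "truth_expected.csv")


def generate_study(
    specs: list[PopulationSpec], seed: int, render_lanes: bool = True
) -> SyntheticStudy:
    """Generate a full deterministic study for the given population specs.

    One shared ladder lane accompanies the sample lanes.  Identical seeds
    give identical studies; ``render_lanes=False`` skips gel rendering for
    large chemotype/profile-only simulations.
    """
    ids = [s.population_id for s in specs]
    if len(set(ids)) != len(ids):
        raise SyntheticDataError("duplicate population ids in specs")
    if len(specs) < 1:
        raise SyntheticDataError("need at least one population spec")
    rng = np.random.default_rng(seed)

    peak_records: list[GCPeakRecord] = []
    profiles: list[ITSProfile] = []
    lanes: list[GelLane] = [make_ladder_lane()] if render_lanes else []
    truth_rows = []
    for spec in specs:
        for k in range(spec.n_plants):
            plant_id = f"{spec.population_id}_{k:04d}"
            record, truth = sample_plant_chemotype(spec, rng, plant_id=plant_id)
            profile = sample_its_profile(spec, rng, plant_id=plant_id)
            peak_records.append(record)
            profiles.append(profile)
            if render_lanes:
                lane, _ = render_gel_lane(
                    profile,
                    total_intensity=spec.total_intensity,
                    noise_cv_band=spec.noise_cv_band,
                    rng=rng,
                    lane_id=f"lane_{plant_id}",
                )
                lanes.append(lane)
            truth_rows.append(
                {
                    "population_id": spec.population_id,
                    **truth,
                    "itsA": profile.itsA,
                    "itsB": profile.itsB,
                    "itsC": profile.itsC,
                }
            )

    expected = pd.DataFrame(
        {s.population_id: s.expected_frequencies() for s in specs}
    ).T.rename_axis("population")
    return SyntheticStudy(
        specs=list(specs),
        peak_records=peak_records,
        profiles=profiles,
        lanes=lanes,
        truth_per_plant=pd.DataFrame(truth_rows),
        truth_expected=expected,
    )


def default_population_specs(
    n_plants: int = 17, noise_cv_band: float = 0.04
) -> list[PopulationSpec]:
    """Population specs parameterized from the packaged reference survey.

    Genotype-group proportions come from each population's fp under
    maximal-heterozygosity allocation; the erc Beta matches the reference
    mean and SD; the ITS Dirichlet concentration is fitted from the itsB SD
    (the largest-variance component).
    """
    from .distances import load_reference_frame

    frame = load_reference_frame()
    specs = []
    for population, row in frame.iterrows():
        its = np.array([row["itsA"], row["itsB"], row["itsC"]])
        its = its / its.sum()
        b, sd_b = float(its[1]), max(float(row["itsB_sd"]), 0.01)
        concentration = max(b * (1.0 - b) / (sd_b * sd_b) - 1.0, 1.0)
        specs.append(
            PopulationSpec(
                population_id=str(population),
                n_plants=n_plants,
                group_props=group_props_from_fp(float(row["fp"])),
                erc_mean=float(row["erc"]),
                erc_spread=float(row["erc_sd"]),
                its_target=(float(its[0]), float(its[1]), float(its[2])),
                its_concentration=concentration,
                noise_cv_band=noise_cv_band,
            )
        )
    return specs
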