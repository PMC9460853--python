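"""End-to-end orchestration: raw tables or synthetic data to frequency tables,
chord-distance matrices, NJ phenograms and a topology report.

The run proceeds chemotypes -> densitometry -> distances -> trees.  Inputs
can be (a) a ready population frequency table, (b) per-plant GC peak and gel
band tables, or (c) synthetic population specs.  Every enabled mode
(chemical / genetic / combined) yields a distance matrix and a Newick
phenogram; topology findings (tightest sister pair, outermost leaf) and
pattern-validation warnings are collected in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from . import chemotypes as chem
from . import rflp_densitometry as rflp
from .distances import (
    FrequencyTable,
    distance_matrix,
    load_reference_table,
    read_frequency_table,
    write_phylip,
)
from .nj_tree import neighbor_joining, outermost_leaf, tight_pair, to_newick
from .synthetic_data import (
    LADDER_SIZES,
    PopulationSpec,
    SyntheticStudy,
    generate_study,
)

__all__ = [
    "PipelineError",
    "RunConfig",
    "RunReport",
    "run",
    "compare_topologies",
    "REFERENCE_ASSERTIONS",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


#: Clustering statements reported for the nine-population reference survey,
#: as declarative topology assertions checkable against a run's trees.
REFERENCE_ASSERTIONS: tuple[dict, ...] = (
    {"mode": "chemical", "type": "sisters", "leaves": ("Ankaran", "Padna")},
    {"mode": "chemical", "type": "outermost", "leaf": "Rabac"},
    {"mode": "genetic", "type": "sisters", "leaves": ("Flengi", "Padna")},
    {"mode": "combined", "type": "clade",
     "leaves": ("Ankaran", "Buje", "Rovinj", "Liznjan")},
    {"mode": "combined", "type": "clade", "leaves": ("Flengi", "Padna", "Vodnjan")},
    {"mode": "combined", "type": "outermost", "leaf": "Rabac"},
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input source is used, in precedence order: ``frequency_table``
    (path or :class:`FrequencyTable`), ``synthetic`` (population specs), or
    ``peak_table`` + ``band_table`` paths.
    """

    frequency_table: object | None = None
    peak_table: object | None = None
    band_table: object | None = None
    synthetic: list[PopulationSpec] | None = None
    modes: tuple[str, ...] = ("chemical", "genetic", "combined")
    variant: str = "angular_mean"
    band_tolerance: float = 0.05
    fenchone_threshold: float = 15.0
    outdir: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fenchone_threshold < 100.0:
            raise PipelineError("config: fenchone threshold must be in (0, 100)")
        if not self.modes:
            raise PipelineError("config: at least one mode must be enabled")
        if (
            self.frequency_table is None
            and self.synthetic is None
            and (self.peak_table is None or self.band_table is None)
        ):
            raise PipelineError(
                "config: provide a frequency table, synthetic specs, or both a "
                "peak table and a band table"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = [PopulationSpec(**spec) for spec in raw["synthetic"]]
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        return cls(**raw)


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    frequency_table: FrequencyTable
    matrices: dict[str, DistanceMatrix]
    trees: dict[str, TreeNode] = field(repr=False)
    newick: dict[str, str]
    topology: dict[str, dict]
    warnings: list[str]
    study: SyntheticStudy | None = field(default=None, repr=False)


def _chemical_frequencies(records, threshold):
    plants = [chem.compute_relative_contents(r, threshold=threshold) for r in records]
    by_pop: dict[str, list] = {}
    for p in plants:
        by_pop.setdefault(p.population_id, []).append(p)
    rows = {}
    for pop, group in by_pop.items():
        s = chem.pool_population(group)
        rows[pop] = {"fp": s.fp, "fa": s.fa, "erc": s.erc_mean, "arc": s.arc_mean}
    return rows, plants


def _its_frequencies(lanes, tolerance, warnings):
    ladders = [lane for lane in lanes if lane.is_ladder]
    if not ladders:
        raise PipelineError("densitometry: no ladder lane found in band table")
    calibration = rflp.calibrate_ladder(ladders[0], list(LADDER_SIZES))
    profiles = []
    for lane in lanes:
        if lane.is_ladder:
            continue
        match = rflp.match_diagnostic_bands(lane, calibration, tolerance_frac=tolerance)
        report = rflp.validate_pattern(match)
        for w in report.warnings:
            warnings.append(f"lane {lane.lane_id}: {w}")
        plant = lane.plant_id if lane.plant_id else lane.lane_id
        profiles.append(rflp.profile_from_match(match, plant_id=plant))
    return profiles


def run(config: RunConfig) -> RunReport:
    """Execute the pipeline and (optionally) write all artifacts to outdir.

    Analysis on a ready frequency table touches no RNG and is fully
    deterministic; synthetic runs are deterministic given ``config.seed``.
    Any stage failure aborts before anything is written.
    """
    warnings: list[str] = []
    study = None

    if config.frequency_table is not None:
        table = (
            config.frequency_table
            if isinstance(config.frequency_table, FrequencyTable)
            else read_frequency_table(config.frequency_table)
        )
    else:
        if config.synthetic is not None:
            try:
                study = generate_study(config.synthetic, seed=config.seed)
            except Exception as exc:
                raise PipelineError(f"synthetic: {exc}") from exc
            records, lanes = study.peak_records, study.lanes
        else:
            try:
                records = chem.read_peak_table(config.peak_table)
                lanes = rflp.read_band_table(config.band_table)
            except Exception as exc:
                raise PipelineError(f"input: {exc}") from exc
        try:
            chem_rows, _ = _chemical_frequencies(records, config.fenchone_threshold)
        except Exception as exc:
            raise PipelineError(f"chemotypes: {exc}") from exc
        try:
            profiles = _its_frequencies(lanes, config.band_tolerance, warnings)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"densitometry: {exc}") from exc

        pop_of_plant = {r.plant_id: r.population_id for r in records}
        its_by_pop: dict[str, list] = {}
        for profile in profiles:
            pop = pop_of_plant.get(profile.plant_id)
            if pop is None:
                warnings.append(f"profile {profile.plant_id}: no matching peak record")
                continue
            its_by_pop.setdefault(pop, []).append(profile.as_array())
        frame_rows = {}
        for pop, chem_row in chem_rows.items():
            if pop not in its_by_pop:
                raise PipelineError(f"densitometry: population {pop} has no ITS profiles")
            mean = pd.DataFrame(its_by_pop[pop]).mean(axis=0)
            frame_rows[pop] = {
                **chem_row,
                "itsA": mean[0], "itsB": mean[1], "itsC": mean[2],
            }
        frame = pd.DataFrame(frame_rows).T.rename_axis("population")
        table = FrequencyTable(frame)

    matrices, trees, newick, topology = {}, {}, {}, {}
    for mode in config.modes:
        try:
            dm = distance_matrix(table, mode=mode, variant=config.variant)
            tree = neighbor_joining(dm)
        except Exception as exc:
            raise PipelineError(f"{mode}: {exc}") from exc
        matrices[mode] = dm
        trees[mode] = tree
        newick[mode] = to_newick(tree)
        pair = tight_pair(tree) if len(table) >= 4 else None
        outer = outermost_leaf(tree)
        if pair is not None and pair.tied:
            warnings.append(f"{mode}: tight-pair tie broken lexicographically")
        if outer.tied:
            warnings.append(f"{mode}: outermost-leaf tie broken lexicographically")
        topology[mode] = {
            "tight_pair": list(pair.leaves) if pair else None,
            "tight_pair_distance": pair.distance if pair else None,
            "outermost": outer.leaf,
            "outermost_mean_distance": outer.mean_distance,
        }

    report = RunReport(
        frequency_table=table,
        matrices=matrices,
        trees=trees,
        newick=newick,
        topology=topology,
        warnings=warnings,
        study=study,
    )
    if config.outdir is not None:
        _write_report(report, config.outdir)
    return report


def _write_report(report: RunReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.frequency_table.frame.to_csv(outdir / "frequency_table.csv")
    for mode, dm in report.matrices.items():
        dm.to_data_frame().to_csv(outdir / f"distances_{mode}.csv")
        write_phylip(dm, outdir / f"distances_{mode}.phy")
        (outdir / f"tree_{mode}.nwk").write_text(report.newick[mode] + "\n")
    summary = {"topology": report.topology, "warnings": report.warnings}
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _leaf_set(tree: TreeNode) -> set[str]:
    return {tip.name for tip in tree.tips()}


def _is_split(tree: TreeNode, leaves: set[str]) -> bool:
    """True when an edge of the unrooted tree separates ``leaves`` from the rest."""
    all_leaves = _leaf_set(tree)
    for node in tree.traverse(include_self=False):
        below = {tip.name for tip in node.tips()} if not node.is_tip() else {node.name}
        if below == leaves or (all_leaves - below) == leaves:
            return True
    return False


def _are_sisters(tree: TreeNode, a: str, b: str) -> bool:
    tip_a = tree.find(a)
    tip_b = tree.find(b)
    return tip_a.parent is tip_b.parent


def compare_topologies(report: RunReport, assertions) -> list[dict]:
    """Check declarative topology assertions against the run's trees.

    Supported assertion types: ``sisters`` (two leaves share a node),
    ``clade`` (the leaf set forms a clade on the tree rooted at the
    outermost leaf), ``outermost`` (a named leaf is outermost).  Referencing
    an unknown leaf raises ``ValueError``.
    """
    results = []
    for assertion in assertions:
        mode = assertion["mode"]
        if mode not in report.trees:
            raise ValueError(f"assertion references disabled mode {mode!r}")
        tree = report.trees[mode]
        known = _leaf_set(tree)
        kind = assertion["type"]
        if kind == "outermost":
            names = [assertion["leaf"]]
        else:
            names = list(assertion["leaves"])
        unknown = [n for n in names if n not in known]
        if unknown:
            raise ValueError(f"assertion references unknown leaves {unknown}")

        if kind == "sisters":
            a, b = names
            passed = _are_sisters(tree, a, b)
            detail = f"{a} and {b} {'share' if passed else 'do not share'} a node"
        elif kind == "clade":
            leaves = set(names)
            root = report.topology[mode]["outermost"]
            passed = root not in leaves and _is_split(tree, leaves)
            detail = (
                f"{sorted(leaves)} {'forms' if passed else 'does not form'} a clade "
                f"rooted at {root}"
            )
        elif kind == "outermost":
            passed = report.topology[mode]["outermost"] == names[0]
            detail = f"outermost leaf is {report.topology[mode]['outermost']}"
        else:
            raise ValueError(f"unknown assertion type {kind!r}")
        results.append({"assertion": dict(assertion), "passed": bool(passed), "detail": detail})
    return results


def run_reference(variant: str = "angular_mean") -> RunReport:
    """Run the analysis stages on the packaged reference frequency table."""
    return run(RunConfig(frequency_table=load_reference_table(), variant=variant))


def variant_topology_report(assertions=REFERENCE_ASSERTIONS) -> dict[str, list[dict]]:
    """Evaluate topology assertions on the reference table under every
    chord-distance variant, flagging which variant reproduces which statement.

    The published phenograms come from legacy software whose exact chord
    constant is not stated; this report makes the robustness of each
    clustering statement to that choice explicit.
    """
    from .distances import VARIANTS

    return {
        variant: compare_topologies(run_reference(variant=variant), assertions)
        for variant in VARIANTS
    }
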