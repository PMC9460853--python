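"""Multi-locus frequency tables and Cavalli-Sforza & Edwards chord distances.

Three putative loci characterize each fennel population: fenchone
(alleles fp/fa, from the 0/1/2 score), phenylpropanoid (erc/arc, from
GC peak-area ratios), and the nrDNA ITS locus (itsA/itsB/itsC, from gel
densitometry).  Between two populations with allele-frequency vectors
``p_l`` and ``q_l`` at locus ``l`` the per-locus chord distance is

    d_l = (2/pi) * sqrt(2 * (1 - sum_j sqrt(p_lj * q_lj)))

and the multi-locus distance averages d_l over loci (default variant).
Distances can be computed in *chemical* (fenchone + phenylpropanoid),
*genetic* (ITS only) or *combined* (all three loci) mode.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "CHORD_MAX",
    "LOCI",
    "MODE_LOCI",
    "VARIANTS",
    "Locus",
    "FrequencyTable",
    "FrequencyError",
    "chord_distance",
    "distance_matrix",
    "load_reference_table",
    "read_frequency_table",
    "write_phylip",
    "read_phylip",
]


class FrequencyError(ValueError):
    """Invalid allele-frequency input."""


class Locus(NamedTuple):
    name: str
    alleles: tuple[str, ...]


LOCI: tuple[Locus, ...] = (
    Locus("fenchone", ("fp", "fa")),
    Locus("phenylpropanoid", ("erc", "arc")),
    Locus("its", ("itsA", "itsB", "itsC")),
)

MODE_LOCI: dict[str, tuple[str, ...]] = {
    "chemical": ("fenchone", "phenylpropanoid"),
    "genetic": ("its",),
    "combined": ("fenchone", "phenylpropanoid", "its"),
}

#: Per-locus chord-distance maximum, attained for disjoint allele support.
CHORD_MAX = (2.0 / math.pi) * math.sqrt(2.0)

#: Chord-distance variants (legacy software differs in constants):
#: ``angular_mean`` (default) averages (2/pi)*sqrt(2(1-s_l)) over loci;
#: ``pooled`` applies (2*sqrt(2)/pi) once to the root of the locus-averaged
#: radicand; ``unscaled`` omits the 2/pi factor.
VARIANTS = ("angular_mean", "pooled", "unscaled")

_ALL_COLUMNS = tuple(a for locus in LOCI for a in locus.alleles)


def _loci_by_name(names: Sequence[str]) -> tuple[Locus, ...]:
    table = {l.name: l for l in LOCI}
    try:
        return tuple(table[n] for n in names)
    except KeyError as exc:
        raise FrequencyError(f"unknown locus {exc.args[0]!r}") from None


class FrequencyTable:
    """Population x allele frequency table over the three study loci.

    Wraps a DataFrame indexed by population with columns fp, fa, erc, arc,
    itsA, itsB, itsC.  Each locus block must sum to 1; rounding-level
    deviations up to ``renorm_tol`` are renormalized (printed tables carry
    3 decimals), larger deviations are errors.
    """

    def __init__(self, frame: pd.DataFrame, renorm_tol: float = 1e-6):
        missing = set(_ALL_COLUMNS) - set(frame.columns)
        if missing:
            raise FrequencyError(f"frequency table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(_ALL_COLUMNS)].astype(float).copy()
        if frame.index.has_duplicates:
            raise FrequencyError("duplicate population ids")
        for locus in LOCI:
            block = frame.loc[:, list(locus.alleles)]
            if (block < -1e-12).any().any() or (block > 1 + 1e-12).any().any():
                raise FrequencyError(f"{locus.name}: frequencies outside [0, 1]")
            sums = block.sum(axis=1)
            bad = sums[(sums - 1.0).abs() > renorm_tol]
            if len(bad):
                raise FrequencyError(
                    f"{locus.name}: frequencies for {list(bad.index)} sum to "
                    f"{bad.iloc[0]:.6f}, not 1"
                )
            frame.loc[:, list(locus.alleles)] = block.div(sums, axis=0)
        self.frame = frame

    @property
    def populations(self) -> list[str]:
        return list(self.frame.index)

    def locus_vectors(self, population: str, loci: Sequence[str]) -> list[np.ndarray]:
        """Per-locus allele-frequency vectors for one population."""
        row = self.frame.loc[population]
        return [row[list(l.alleles)].to_numpy(dtype=float) for l in _loci_by_name(loci)]

    def __len__(self) -> int:
        return len(self.frame)


def chord_distance(
    p: Sequence[np.ndarray],
    q: Sequence[np.ndarray],
    variant: str = "angular_mean",
) -> float:
    """Chord distance between two populations from per-locus frequency vectors.

    ``p`` and ``q`` are parallel sequences of per-locus allele-frequency
    vectors with identical allele ordering.  Vectors must sum to 1 within
    1e-6 (and are renormalized); negative radicands from rounding are clamped
    to 0.
    """
    if variant not in VARIANTS:
        raise FrequencyError(f"unknown chord-distance variant {variant!r}")
    if len(p) != len(q) or len(p) == 0:
        raise FrequencyError("p and q must cover the same non-empty set of loci")
    radicands = []
    for pl, ql in zip(p, q):
        pl = np.asarray(pl, dtype=float)
        ql = np.asarray(ql, dtype=float)
        if pl.shape != ql.shape:
            raise FrequencyError("mismatched allele counts at a locus")
        for v in (pl, ql):
            if np.any(v < -1e-12):
                raise FrequencyError("negative allele frequency")
            if abs(v.sum() - 1.0) > 1e-6:
                raise FrequencyError(f"frequency vector sums to {v.sum():.8f}, not 1")
        pl = pl / pl.sum()
        ql = ql / ql.sum()
        radicands.append(max(0.0, 1.0 - float(np.sqrt(pl * ql).sum())))

    if variant == "angular_mean":
        return float(np.mean([(2.0 / math.pi) * math.sqrt(2.0 * r) for r in radicands]))
    if variant == "pooled":
        return (2.0 * math.sqrt(2.0) / math.pi) * math.sqrt(float(np.mean(radicands)))
    return float(np.mean([math.sqrt(2.0 * r) for r in radicands]))


def distance_matrix(
    table: FrequencyTable, mode: str = "combined", variant: str = "angular_mean"
) -> DistanceMatrix:
    """All pairwise chord distances between the table's populations."""
    if mode not in MODE_LOCI:
        raise FrequencyError(f"unknown mode {mode!r}; expected one of {sorted(MODE_LOCI)}")
    pops = table.populations
    if len(pops) < 2:
        raise FrequencyError("need at least two populations")
    loci = MODE_LOCI[mode]
    vectors = {pop: table.locus_vectors(pop, loci) for pop in pops}
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = chord_distance(vectors[pops[i]], vectors[pops[j]], variant=variant)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values, ids=pops)


def read_frequency_table(path, renorm_tol: float = 0.01) -> FrequencyTable:
    """Read a population frequency table CSV (``population`` + 7 allele columns).

    ``renorm_tol`` defaults to 0.01 because printed tables carry 3 decimals
    and locus blocks can sum to 0.999.
    """
    frame = pd.read_csv(path, comment="#")
    if "population" not in frame.columns:
        raise FrequencyError("frequency table needs a 'population' column")
    frame = frame.set_index("population")
    return FrequencyTable(frame, renorm_tol=renorm_tol)


def load_reference_table() -> FrequencyTable:
    """The packaged nine-population Istrian reference frequency table."""
    ref = resources.files("fennelpop.data") / "reference_frequencies.csv"
    with resources.as_file(ref) as path:
        return read_frequency_table(path)


def load_reference_frame() -> pd.DataFrame:
    """Raw reference table (averages and SD columns, un-renormalized)."""
    ref = resources.files("fennelpop.data") / "reference_frequencies.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#").set_index("population")


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for label, row in zip(dm.ids, dm.data):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<10s} {cells}\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a PHYLIP square-format distance matrix."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise FrequencyError("empty PHYLIP file")
    n = int(tokens[0])
    labels, rows = [], []
    k = 1
    for _ in range(n):
        labels.append(tokens[k])
        rows.append([float(t) for t in tokens[k + 1 : k + 1 + n]])
        k += 1 + n
    return DistanceMatrix(np.array(rows), ids=labels)
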