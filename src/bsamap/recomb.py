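"""Recombinant-mapping arithmetic for interval refinement.

Phenotypically mutant animals are homozygous at the causative locus; a
heterozygous genotype at a linked marker marks a recombination event
between marker and locus.  The recombination frequency Rf =
recombinants/genotyped converts to physical distance via the species
map density (zebrafish: 1 cM ~ 0.74 Mb), and the run structure of
heterozygous markers along the chromosome excludes regions from the
mapped interval.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .snp_index import MappedInterval

__all__ = [
    "HOM_MUT",
    "HET",
    "UNKNOWN",
    "SpeciesParams",
    "MarkerGenotypeTable",
    "RecombinationEstimate",
    "RefinementResult",
    "recombination_frequency",
    "distance_estimate",
    "infer_missing_genotypes",
    "refine_interval",
    "locus_position_estimate",
    "pairing_probability",
    "genomes_screened",
    "read_genotype_table",
    "write_genotype_table",
]

HOM_MUT = "hom_mut"
HET = "het"
UNKNOWN = "unknown"

_CELL = {HOM_MUT: "M", HET: "H", UNKNOWN: "?"}
_CELL_INV = {v: k for k, v in _CELL.items()}


@dataclass(frozen=True)
class SpeciesParams:
    """Genetic-to-physical map density (Mb per centimorgan)."""

    mb_per_cm: float = 0.74

    def __post_init__(self) -> None:
        if self.mb_per_cm <= 0:
            raise ValueError("mb_per_cm must be > 0")


@dataclass
class MarkerGenotypeTable:
    """Animals x ordered markers, genotypes in {hom_mut, het, unknown}.

    All markers lie on one chromosome and are stored sorted by position.
    """

    chrom: str
    positions: List[int]  # bp, strictly increasing
    animals: List[str]
    genotypes: Dict[str, List[str]]  # animal -> genotype per marker
    inferred: Set[Tuple[str, int]] = field(default_factory=set)  # (animal, marker idx)

    def __post_init__(self) -> None:
        order = sorted(range(len(self.positions)), key=lambda i: self.positions[i])
        if order != list(range(len(self.positions))):
            self.positions = [self.positions[i] for i in order]
            self.genotypes = {a: [g[i] for i in order] for a, g in self.genotypes.items()}
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("marker positions must be strictly increasing")
        for a in self.animals:
            row = self.genotypes[a]
            if len(row) != len(self.positions):
                raise ValueError(f"animal {a}: {len(row)} genotypes for {len(self.positions)} markers")
            bad = set(row) - {HOM_MUT, HET, UNKNOWN}
            if bad:
                raise ValueError(f"animal {a}: unknown genotype codes {bad}")


@dataclass
class RecombinationEstimate:
    """Rf at one marker and the physical distance it implies."""

    chrom: str
    position: int
    recombinants: int
    genotyped: int
    distance_mb: Optional[float] = None

    @property
    def rf(self) -> float:
        return self.recombinants / self.genotyped


@dataclass
class RefinementResult:
    interval: MappedInterval
    exclusions: Dict[str, List[Tuple[int, int]]]  # animal -> excluded [lo, hi] spans
    conflicts: List[str]  # animals implying double crossovers, excluded


def recombination_frequency(table: MarkerGenotypeTable, marker_index: int) -> RecombinationEstimate:
    """Rf = heterozygous / genotyped mutant animals at one marker."""
    recomb = genotyped = 0
    for a in table.animals:
        g = table.genotypes[a][marker_index]
        if g == UNKNOWN:
            continue
        genotyped += 1
        if g == HET:
            recomb += 1
    if genotyped == 0:
        raise ValueError(f"no animal genotyped at marker index {marker_index}")
    return RecombinationEstimate(table.chrom, table.positions[marker_index], recomb, genotyped)


def distance_estimate(est: RecombinationEstimate, sp: SpeciesParams = SpeciesParams()) -> float:
    """Physical distance to the locus: Rf (fraction) x 100 cM x Mb/cM.

    No map-function correction is applied (raw Rf).  Report
    ``round(distance)`` for the integer-Mb convention.
    """
    return est.rf * 100.0 * sp.mb_per_cm


def infer_missing_genotypes(table: MarkerGenotypeTable) -> MarkerGenotypeTable:
    """Fill unknowns flanked by identical known genotypes.

    An unknown whose nearest known genotype on each side is the same value
    is set to that value and flagged in ``inferred``.  Edge unknowns and
    unknowns between discordant neighbours are left alone.  Known
    genotypes are never altered.
    """
    new_genos: Dict[str, List[str]] = {}
    inferred = set(table.inferred)
    for a in table.animals:
        row = list(table.genotypes[a])
        for i, g in enumerate(row):
            if g != UNKNOWN:
                continue
            left = next((row[j] for j in range(i - 1, -1, -1) if table.genotypes[a][j] != UNKNOWN), None)
            right = next((row[j] for j in range(i + 1, len(row)) if table.genotypes[a][j] != UNKNOWN), None)
            if left is not None and left == right:
                row[i] = left
                inferred.add((a, i))
        new_genos[a] = row
    return MarkerGenotypeTable(table.chrom, list(table.positions), list(table.animals), new_genos, inferred)


def _runs(known: Sequence[Tuple[int, str]]) -> Tuple[List[int], List[int], bool]:
    """Prefix/suffix het runs over the known-genotype sequence.

    Returns (prefix het marker indices, suffix het marker indices,
    interior_conflict).  ``known`` is [(marker index, genotype)] in
    position order with no unknowns.
    """
    genos = [g for _, g in known]
    n = len(genos)
    p = 0
    while p < n and genos[p] == HET:
        p += 1
    s = 0
    while s < n - p and genos[n - 1 - s] == HET:
        s += 1
    interior = any(
        genos[i] == HET and any(g == HOM_MUT for g in genos[:i]) and any(g == HOM_MUT for g in genos[i + 1 :])
        for i in range(n)
    )
    prefix = [known[i][0] for i in range(p)]
    suffix = [known[n - 1 - i][0] for i in range(s)][::-1]
    return prefix, suffix, interior


def refine_interval(interval: MappedInterval, table: MarkerGenotypeTable) -> RefinementResult:
    """Shrink the mapped interval using per-animal recombination structure.

    For each animal the maximal run of heterozygous markers starting at
    the left (right) end of the marker order excludes
    [interval.left, innermost left-run marker] ([innermost right-run
    marker, interval.right]).  Heterozygous markers strictly between
    homozygous ones imply a double crossover; such animals are flagged
    conflicting and excluded.  An animal heterozygous at *every*
    genotyped marker is directionally ambiguous; it is oriented so the
    refined interval stays nonempty (preferring the smaller exclusion,
    ties to the left).  Raises if refinement empties the interval.
    """
    if table.chrom != interval.chrom:
        raise ValueError(f"genotype table is on {table.chrom}, interval on {interval.chrom}")
    pos = table.positions

    exclusions: Dict[str, List[Tuple[int, int]]] = {}
    conflicts: List[str] = []
    ambiguous: List[Tuple[str, int, int]] = []  # (animal, first het marker idx, last het marker idx)
    left, right = interval.left, interval.right

    for a in table.animals:
        known = [(i, g) for i, g in enumerate(table.genotypes[a]) if g != UNKNOWN]
        if not known:
            continue
        prefix, suffix, interior = _runs(known)
        if interior:
            conflicts.append(a)
            continue
        if prefix and len(prefix) == len(known):  # het everywhere: ambiguous orientation
            ambiguous.append((a, prefix[0], prefix[-1]))
            continue
        spans: List[Tuple[int, int]] = []
        if prefix:
            spans.append((interval.left, pos[prefix[-1]]))
        if suffix:
            spans.append((pos[suffix[0]], interval.right))
        if spans:
            exclusions[a] = spans
            for lo, hi in spans:
                if lo == interval.left:
                    left = max(left, hi)
                if hi == interval.right:
                    right = min(right, lo)

    for a, first, last in ambiguous:
        opt_left = pos[last]  # exclude [interval.left, last het marker]
        opt_right = pos[first]  # exclude [first het marker, interval.right]
        feas_l = max(left, opt_left) < right
        feas_r = left < min(right, opt_right)
        if feas_l and feas_r:
            take_left = (opt_left - interval.left) <= (interval.right - opt_right)
        elif feas_l or feas_r:
            take_left = feas_l
        else:
            conflicts.append(a)
            continue
        if take_left:
            exclusions[a] = [(interval.left, opt_left)]
            left = max(left, opt_left)
        else:
            exclusions[a] = [(opt_right, interval.right)]
            right = min(right, opt_right)

    if left >= right:
        bad = sorted(exclusions)
        raise ValueError(f"refinement empties the interval; incompatible animals: {bad}")
    argmax = min(max(interval.argmax, left), right)
    refined = MappedInterval(interval.chrom, left, right, argmax, interval.peak)
    return RefinementResult(refined, exclusions, conflicts)


def locus_position_estimate(
    estimates: Sequence[RecombinationEstimate],
    refined: MappedInterval,
    sp: SpeciesParams = SpeciesParams(),
) -> Tuple[float, float, List[bool]]:
    """Average predicted locus position from all markers.

    Each marker predicts the locus at marker ± distance; the sign landing
    inside the refined interval is chosen (or the candidate nearest the
    interval, flagged).  Returns (mean bp, sample SD bp, out-of-interval
    flags).  With a single marker the SD is reported as 0.
    """
    if not estimates:
        raise ValueError("at least one marker estimate required")
    picks: List[float] = []
    flags: List[bool] = []
    for est in estimates:
        d_bp = (est.distance_mb if est.distance_mb is not None else distance_estimate(est, sp)) * 1e6
        cands = [est.position - d_bp, est.position + d_bp]
        inside = [c for c in cands if refined.left <= c <= refined.right]
        if inside:
            picks.append(min(inside, key=lambda c: abs(c - est.position)) if len(inside) > 1 else inside[0])
            flags.append(False)
        else:
            def dist_to_interval(c: float) -> float:
                return max(refined.left - c, c - refined.right, 0.0)

            picks.append(min(cands, key=dist_to_interval))
            flags.append(True)
    mean = sum(picks) / len(picks)
    if len(picks) > 1:
        sd = math.sqrt(sum((p - mean) ** 2 for p in picks) / (len(picks) - 1))
    else:
        sd = 0.0
    return mean, sd, flags


def pairing_probability(n_crosses: int, carrier_fraction: float = 0.5) -> float:
    """P(at least one incross pairs two carriers) = 1 - (1 - q^2)^n.

    With carrier fraction q = 1/2 among F2 fish this is 1 - 0.75^n.
    """
    if n_crosses < 0:
        raise ValueError("n_crosses must be >= 0")
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    return 1.0 - (1.0 - carrier_fraction**2) ** n_crosses


def genomes_screened(pairs_per_family: Sequence[int], carrier_fraction: float = 0.5) -> float:
    """Expected number of genomes screened: sum of per-family pairing probabilities."""
    return sum(pairing_probability(n, carrier_fraction) for n in pairs_per_family)


# ---------------------------------------------------------------------------
# marker genotype table TSV: first column animal id, one column per marker
# named "chrom:pos", cells in {M, H, ?}


def read_genotype_table(path: str | os.PathLike) -> MarkerGenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        marker_cols = header[1:]
        chroms, positions = [], []
        for col in marker_cols:
            chrom, _, p = col.rpartition(":")
            chroms.append(chrom)
            positions.append(int(p))
        if len(set(chroms)) > 1:
            raise ValueError(f"{path}: markers span multiple chromosomes {sorted(set(chroms))}")
        animals: List[str] = []
        genotypes: Dict[str, List[str]] = {}
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            animal, row = cells[0], cells[1:]
            animals.append(animal)
            genotypes[animal] = [_CELL_INV.get(c.strip(), UNKNOWN) for c in row]
    return MarkerGenotypeTable(chroms[0], positions, animals, genotypes)


def write_genotype_table(table: MarkerGenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal\t" + "\t".join(f"{table.chrom}:{p}" for p in table.positions) + "\n")
        for a in table.animals:
            fh.write(a + "\t" + "\t".join(_CELL[g] for g in table.genotypes[a]) + "\n")
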