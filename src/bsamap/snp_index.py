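"""Windowed heterozygosity, the SNP-index statistic, and interval selection.

The mapping signal: in an incross of heterozygous carriers, phenotypically
mutant offspring are homozygous at the causative locus and (by linkage) in
the surrounding region, while their phenotypically wild-type siblings stay
heterozygous there.  Counting heterozygous variant sites in tiled windows
for each pool and forming

    SNP_index(C) = (Het_wt(C) - Het_mut(C)) / (2 + Het_mut(C))

yields a statistic that is large and positive where the mutant pool has
lost heterozygosity.  A moving average over a genetic-map-scale width
(750 kb ~ 1 cM in zebrafish) smooths window noise; the candidate interval
is the region around the genome-wide maximum bounded on each side by the
smoothed index crossing zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats import GenomeIndex, VariantCall

__all__ = [
    "IndexConfig",
    "HetTrack",
    "SnpIndexTrack",
    "MappedInterval",
    "is_heterozygous_point",
    "window_heterozygosity",
    "snp_index",
    "moving_average",
    "select_interval",
    "mean_local_index",
]


class NoPositiveSignalError(RuntimeError):
    """The smoothed SNP index is nowhere positive: no homozygous region detected."""


@dataclass(frozen=True)
class IndexConfig:
    """Tunable parameters of the homozygosity-mapping statistic.

    window_width/window_step
        Tiling 10-kb windows by default; step may be smaller for overlap.
    ma_width
        Moving-average width in bp (default 750 kb, ~1 cM in zebrafish).
    het_min_each / het_ratio_bounds
        A variant site counts as a heterozygous point when both alleles
        have at least ``het_min_each`` reads and RO/AO lies inside the
        ratio bounds (inclusive).
    min_chrom_len
        Sequences shorter than this are excluded from mapping.
    """

    window_width: int = 10_000
    window_step: int = 10_000
    ma_width: int = 750_000
    het_min_each: int = 2
    het_ratio_bounds: Tuple[float, float] = (0.25, 4.0)
    min_chrom_len: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")
        if not (0 < self.window_step <= self.window_width):
            raise ValueError("window_step must satisfy 0 < step <= window_width")
        if self.ma_width < self.window_width:
            raise ValueError("ma_width must be >= window_width")
        if self.het_min_each < 1:
            raise ValueError("het_min_each must be >= 1")
        lo, hi = self.het_ratio_bounds
        if not (0 < lo < hi):
            raise ValueError("het_ratio_bounds must satisfy 0 < lo < hi")


@dataclass
class HetTrack:
    """Per-chromosome heterozygous-point counts at window centers.

    ``centers[i]`` is the midpoint of the i-th window's 0-based half-open
    span; with window start s (1-based) and width w that is (s-1) + w/2.
    """

    chrom: str
    centers: np.ndarray  # bp, strictly increasing
    counts: np.ndarray  # int, >= 0


@dataclass
class SnpIndexTrack:
    chrom: str
    centers: np.ndarray
    raw: np.ndarray
    smoothed: Optional[np.ndarray] = None


@dataclass
class MappedInterval:
    """The selected candidate region: [left, right] 1-based inclusive."""

    chrom: str
    left: int
    right: int
    argmax: int  # window center of the genome-wide maximum
    peak: float

    def __post_init__(self) -> None:
        if not (self.left <= self.argmax <= self.right):
            raise ValueError("argmax must lie inside [left, right]")

    @property
    def size(self) -> int:
        return self.right - self.left

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.left <= pos <= self.right


def is_heterozygous_point(call: VariantCall, cfg: IndexConfig = IndexConfig()) -> bool:
    """True iff both alleles are read-supported at a balanced ratio.

    min(ro, ao) >= het_min_each and lo <= ro/ao <= hi.  An absent allele
    (ro or ao = 0) is never heterozygous; no division is performed then.
    """
    if min(call.ro, call.ao) < cfg.het_min_each:
        return False
    lo, hi = cfg.het_ratio_bounds
    ratio = call.ro / call.ao
    return lo <= ratio <= hi


def n_windows(chrom_len: int, cfg: IndexConfig) -> int:
    return max((chrom_len - cfg.window_width) // cfg.window_step + 1, 0)


def window_centers(chrom_len: int, cfg: IndexConfig) -> np.ndarray:
    n = n_windows(chrom_len, cfg)
    starts = 1 + cfg.window_step * np.arange(n)
    return (starts - 1) + cfg.window_width // 2


def window_heterozygosity(
    calls: Iterable[VariantCall],
    genome: GenomeIndex,
    cfg: IndexConfig = IndexConfig(),
) -> Dict[str, HetTrack]:
    """Count heterozygous points per tiled/sliding window for each chromosome.

    Window i (0-based) spans 1-based positions
    [1 + i*step, i*step + window_width]; a call belongs to every window
    whose span contains its position.  Calls on chromosomes absent from
    (or too short for) ``genome`` are skipped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    genome = genome.mappable(cfg.min_chrom_len)
    positions: Dict[str, List[int]] = {name: [] for name in genome.names}
    skipped = 0
    for call in calls:
        if call.chrom not in positions:
            skipped += 1
            continue
        if is_heterozygous_point(call, cfg):
            positions[call.chrom].append(call.pos)
    if skipped:
        log.warning("%d calls on chromosomes outside the genome index were skipped", skipped)

    w, step = cfg.window_width, cfg.window_step
    tracks: Dict[str, HetTrack] = {}
    for name, length in genome.entries:
        n = n_windows(length, cfg)
        counts = np.zeros(n, dtype=np.int64)
        pos = np.asarray(positions[name], dtype=np.int64)
        pos = pos[pos <= length]
        if n and pos.size:
            if step == w:  # tiling fast path
                idx = (pos - 1) // w
                idx = idx[idx < n]
                np.add.at(counts, idx, 1)
            else:
                # window i contains p iff ceil((p-w)/step) <= i <= (p-1)//step
                i_hi = np.minimum((pos - 1) // step, n - 1)
                i_lo = np.maximum(-(-(pos - w) // step), 0)
                for lo, hi in zip(i_lo, i_hi):
                    if lo <= hi:
                        counts[lo : hi + 1] += 1
        tracks[name] = HetTrack(name, window_centers(length, cfg), counts)
    return tracks


def snp_index(het_wt: HetTrack, het_mut: HetTrack) -> SnpIndexTrack:
    """Raw SNP index (Hwt - Hmut) / (2 + Hmut) at shared window centers."""
    if het_wt.chrom != het_mut.chrom or not np.array_equal(het_wt.centers, het_mut.centers):
        raise ValueError("wild-type and mutant tracks must share chromosome and centers")
    hwt = het_wt.counts.astype(float)
    hmut = het_mut.counts.astype(float)
    raw = (hwt - hmut) / (2.0 + hmut)
    return SnpIndexTrack(het_wt.chrom, het_wt.centers.copy(), raw)


def moving_average(track: SnpIndexTrack, cfg: IndexConfig = IndexConfig()) -> SnpIndexTrack:
    """Truncated moving average of the raw index over ±ma_width/2.

    MA(C) = mean of raw values at centers C' with |C' - C| <= ma_width/2;
    at chromosome ends the mean is over the available centers only (no
    zero padding).
    """
    raw = track.raw
    n = raw.size
    k = int(cfg.ma_width // (2 * cfg.window_step))  # neighbours each side
    if n == 0:
        smoothed = raw.copy()
    else:
        csum = np.concatenate([[0.0], np.cumsum(raw)])
        idx = np.arange(n)
        lo = np.maximum(idx - k, 0)
        hi = np.minimum(idx + k, n - 1)
        smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return SnpIndexTrack(track.chrom, track.centers.copy(), raw.copy(), smoothed)


def select_interval(
    tracks: Dict[str, SnpIndexTrack],
    genome: GenomeIndex,
) -> MappedInterval:
    """Zero-bounded interval around the genome-wide smoothed maximum.

    The argmax is taken over all window centers genome-wide (ties broken
    by smallest chromosome name, then smallest center).  Walking outward
    from the argmax, the first center with MA <= 0 stops the walk; the
    bound is the midpoint between that center and its interval-side
    neighbour.  If the walk reaches the chromosome end without a
    non-positive center the bound is 1 (left) or the chromosome length
    (right).
    """
    best: Optional[Tuple[float, str, int, int]] = None  # (value, chrom, center, idx)
    for chrom in sorted(tracks):
        tr = tracks[chrom]
        if tr.smoothed is None:
            raise ValueError(f"track {chrom} has no smoothed values; run moving_average first")
        if tr.smoothed.size == 0:
            continue
        i = int(np.argmax(tr.smoothed))
        v = float(tr.smoothed[i])
        if best is None or v > best[0]:
            best = (v, chrom, int(tr.centers[i]), i)
    if best is None or best[0] <= 0:
        raise NoPositiveSignalError(
            "the smoothed SNP index is nowhere positive; check that the pools "
            "are phenotypically sorted and that the VCFs carry RO/AO counts"
        )
    peak, chrom, argmax_c, i = best
    tr = tracks[chrom]
    ma, centers = tr.smoothed, tr.centers
    length = genome.length(chrom)

    left = 1
    for j in range(i - 1, -1, -1):
        if ma[j] <= 0:
            left = int((centers[j] + centers[j + 1]) // 2)
            break
    right = length
    for j in range(i + 1, ma.size):
        if ma[j] <= 0:
            right = int((centers[j] + centers[j - 1]) // 2)
            break
    return MappedInterval(chrom, left, right, argmax_c, peak)


def map_tracks(
    mut_calls: Iterable[VariantCall],
    wt_calls: Iterable[VariantCall],
    genome: GenomeIndex,
    cfg: IndexConfig = IndexConfig(),
) -> Tuple[Dict[str, SnpIndexTrack], MappedInterval]:
    """Convenience: het tracks -> SNP index -> smoothing -> interval."""
    het_mut = window_heterozygosity(mut_calls, genome, cfg)
    het_wt = window_heterozygosity(wt_calls, genome, cfg)
    tracks = {c: moving_average(snp_index(het_wt[c], het_mut[c]), cfg) for c in het_wt}
    return tracks, select_interval(tracks, genome)


def mean_local_index(track: SnpIndexTrack, position: int, radius: int = 740_000) -> float:
    """Mean raw SNP index over window centers within ±radius of ``position``.

    The default radius of 740 kb each side spans 2 cM total at
    0.74 Mb/cM.  Truncated at chromosome ends; raises if no center is in
    range.
    """
    mask = np.abs(track.centers - position) <= radius
    if not mask.any():
        raise ValueError(f"no window centers within {radius} bp of {track.chrom}:{position}")
    return float(track.raw[mask].mean())
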