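"""Homozygous-point density: the simple comparator to SNP-index mapping.

Instead of contrasting windowed heterozygosity, this method extracts
individual sites that are (near-)homozygous for the alternate allele in
the mutant pool — optionally requiring the sibling pool to be
heterozygous there — and bins their genome-wide density.  Segregating
homozygous points are rare, so the density track is sparse but
concentrates on the causative chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from .formats import GenomeIndex, VariantCall
from .snp_index import IndexConfig, is_heterozygous_point

__all__ = ["HomozygousPoint", "extract_homozygous_points", "point_density"]


@dataclass(frozen=True)
class HomozygousPoint:
    """A site homozygous-alt in the mutant pool."""

    chrom: str
    pos: int
    alt_fraction: float  # mutant ao / (ro + ao)


def extract_homozygous_points(
    mut_calls: Iterable[VariantCall],
    wt_calls: Optional[Iterable[VariantCall]] = None,
    hom_threshold: float = 0.9,
    require_wt_het: bool = True,
    het_cfg: IndexConfig = IndexConfig(),
) -> List[HomozygousPoint]:
    """Sites with mutant alt fraction > ``hom_threshold``.

    With ``require_wt_het`` (and wild-type calls provided) the matched
    sibling call must additionally be a heterozygous point; without
    wild-type calls the sibling condition is skipped (the mutant-only
    variant of the method).  Zero-depth records are skipped.
    """
    wt_by_key: Optional[Mapping] = None
    if wt_calls is not None:
        wt_by_key = {c.key: c for c in wt_calls}
    points: List[HomozygousPoint] = []
    for call in mut_calls:
        depth = call.ro + call.ao
        if depth == 0:
            continue
        frac = call.ao / depth
        if frac <= hom_threshold:
            continue
        if require_wt_het and wt_by_key is not None:
            wt = wt_by_key.get(call.key)
            if wt is None or not is_heterozygous_point(wt, het_cfg):
                continue
        points.append(HomozygousPoint(call.chrom, call.pos, frac))
    return points


def point_density(
    points: Iterable[HomozygousPoint],
    genome: GenomeIndex,
    binwidth: int = 1_000_000,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome binned point counts.

    Bins tile each chromosome as 0-based half-open spans
    [i*binwidth, (i+1)*binwidth); a point at 1-based position p falls in
    bin (p-1)//binwidth.  Returns chrom -> (bin starts, counts).
    """
    density: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for name, length in genome.entries:
        n_bins = (length + binwidth - 1) // binwidth
        starts = binwidth * np.arange(n_bins, dtype=np.int64)
        density[name] = (starts, np.zeros(n_bins, dtype=np.int64))
    for p in points:
        if p.chrom not in density:
            continue
        starts, counts = density[p.chrom]
        idx = (p.pos - 1) // binwidth
        if 0 <= idx < counts.size:
            counts[idx] += 1
    return density
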