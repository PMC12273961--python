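"""Indel marker extraction for recombinant mapping.

Insertions/deletions inside the mapped interval that segregate with the
phenotype are genotypable by PCR product size on a gel, making them
cheap markers for detecting recombinant animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .candidate_filter import SegregationThresholds, segregates_with_phenotype
from .formats import VariantCall
from .snp_index import MappedInterval

__all__ = ["IndelMarker", "extract_indel_markers"]


@dataclass
class IndelMarker:
    """A segregating indel usable as a PCR-size mapping marker.

    ``length_difference`` is the expected product-size shift between the
    two alleles.  ``context`` gives ±context_bp coordinates for external
    primer design.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    length_difference: int
    mut_ro: int
    mut_ao: int
    wt_ro: Optional[int]
    wt_ao: Optional[int]
    context: Tuple[int, int] = (0, 0)

    def to_row(self) -> Dict[str, object]:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "indel_len_diff": self.length_difference,
            "ro_mut": self.mut_ro,
            "ao_mut": self.mut_ao,
            "ro_wt": self.wt_ro,
            "ao_wt": self.wt_ao,
        }


def extract_indel_markers(
    mut_calls: Iterable[VariantCall],
    wt_calls: Iterable[VariantCall],
    interval: MappedInterval,
    thr: SegregationThresholds = SegregationThresholds(),
    min_len_diff: int = 4,
    context_bp: int = 500,
) -> List[IndelMarker]:
    """Segregating indels inside the interval with a gel-resolvable size shift.

    ``min_len_diff`` (default 4 bp) is the smallest allele-length
    difference kept; set to 1 to keep every indel.  Markers pass the same
    segregation predicate as candidate SNPs.  Sorted by position.
    """
    wt_by_key = {c.key: c for c in wt_calls}
    markers: List[IndelMarker] = []
    for call in mut_calls:
        if not interval.contains(call.chrom, call.pos):
            continue
        if not call.is_indel or call.length_difference < min_len_diff:
            continue
        wt = wt_by_key.get(call.key)
        if not segregates_with_phenotype(call, wt, thr):
            continue
        markers.append(
            IndelMarker(
                chrom=call.chrom,
                pos=call.pos,
                ref=call.ref,
                alt=call.alt,
                length_difference=call.length_difference,
                mut_ro=call.ro,
                mut_ao=call.ao,
                wt_ro=wt.ro if wt else None,
                wt_ao=wt.ao if wt else None,
                context=(max(call.pos - context_bp, 1), call.pos + context_bp),
            )
        )
    markers.sort(key=lambda m: (m.chrom, m.pos))
    return markers
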