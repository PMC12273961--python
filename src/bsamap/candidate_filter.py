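"""Segregation, mutagen-likeness, and consequence filters inside the mapped interval.

A candidate point mutation must
  1. segregate with the phenotype: near-absent reference support in the
     mutant pool (RO < 2, AO >= 2 by default) while the wild-type sibling
     pool is heterozygous (1 < RO/AO < 4) or does not report the site;
  2. look ENU-induced: a 1-2 bp same-length substitution;
  3. (when annotations are available) disrupt a gene product: one of
     nonsynonymous, stopgain, stoploss, startloss, or splicing.

Both the unfiltered (all in-interval) and filtered lists are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .effect_annotation import EffectAnnotation, most_severe, severity_rank
from .formats import VariantCall
from .snp_index import MappedInterval

__all__ = [
    "SegregationThresholds",
    "AnnotatedCandidate",
    "segregates_with_phenotype",
    "is_enu_like",
    "filter_candidates",
    "count_candidate_genes",
    "class_tally",
]

#: effect classes retained in the filtered candidate list
REPORTED_CLASSES = frozenset({"nonsynonymous", "stopgain", "stoploss", "startloss", "splicing"})

#: classes that define a "candidate gene" (missense, nonsense, splicing)
GENE_COUNT_CLASSES = frozenset({"nonsynonymous", "stopgain", "splicing"})


@dataclass(frozen=True)
class SegregationThresholds:
    """Read-count thresholds for phenotype segregation.

    mut_max_ro is an exclusive cap (default 2, i.e. RO < 2); the wild-type
    RO/AO ratio bounds are exclusive on both sides.
    """

    mut_max_ro: int = 2
    mut_min_ao: int = 2
    wt_ratio_lo: float = 1.0
    wt_ratio_hi: float = 4.0

    def __post_init__(self) -> None:
        if self.mut_min_ao < 1:
            raise ValueError("mut_min_ao must be >= 1")
        if not (0 < self.wt_ratio_lo < self.wt_ratio_hi):
            raise ValueError("wt ratio bounds must satisfy 0 < lo < hi")


@dataclass
class AnnotatedCandidate:
    """A mutant-pool variant with matched wild-type counts, effect, and SIFT."""

    call: VariantCall  # mutant-pool counts
    wt_ro: Optional[int] = None
    wt_ao: Optional[int] = None
    annotations: Sequence[EffectAnnotation] = ()
    sift: Optional[float] = None

    @property
    def best(self) -> Optional[EffectAnnotation]:
        return most_severe(self.annotations) if self.annotations else None

    @property
    def klass(self) -> Optional[str]:
        ann = self.best
        return ann.klass if ann else None

    def to_row(self) -> Dict[str, object]:
        ann = self.best
        return {
            "chrom": self.call.chrom,
            "pos": self.call.pos,
            "ref": self.call.ref,
            "alt": self.call.alt,
            "ro_mut": self.call.ro,
            "ao_mut": self.call.ao,
            "ro_wt": self.wt_ro,
            "ao_wt": self.wt_ao,
            "gene": ann.gene if ann else None,
            "transcript": ann.transcript if ann else None,
            "region": ann.region if ann else None,
            "effect": ann.effect if ann else None,
            "cdna_change": ann.cdna_change if ann else None,
            "protein_change": ann.protein_change if ann else None,
            "sift": self.sift,
        }


def segregates_with_phenotype(
    mut_call: VariantCall,
    wt_call: Optional[VariantCall],
    thr: SegregationThresholds = SegregationThresholds(),
) -> bool:
    """True iff the variant co-segregates with the mutant phenotype.

    Mutant pool: RO < mut_max_ro and AO >= mut_min_ao.  Wild-type pool:
    absent, or heterozygous with wt_ratio_lo < RO/AO < wt_ratio_hi
    (strict).
    """
    if not (mut_call.ro < thr.mut_max_ro and mut_call.ao >= thr.mut_min_ao):
        return False
    if wt_call is None:
        return True
    if wt_call.ao == 0:
        return False
    ratio = wt_call.ro / wt_call.ao
    return thr.wt_ratio_lo < ratio < thr.wt_ratio_hi


def is_enu_like(call: VariantCall) -> bool:
    """1-2 bp same-length substitutions (the mutagen's signature)."""
    return len(call.ref) == len(call.alt) and len(call.ref) <= 2


def filter_candidates(
    mut_calls: Iterable[VariantCall],
    wt_calls: Iterable[VariantCall],
    interval: MappedInterval,
    annotations: Optional[Mapping[Tuple[str, int, str, str], Sequence[EffectAnnotation]]] = None,
    sift_lookup: Optional[Mapping[Tuple[str, int, str, str], float]] = None,
    thr: SegregationThresholds = SegregationThresholds(),
) -> Tuple[List[AnnotatedCandidate], List[AnnotatedCandidate]]:
    """Candidate lists inside the mapped interval.

    Returns ``(unfiltered, filtered)``.  ``unfiltered`` holds every
    mutant-pool variant inside [left, right]; ``filtered`` holds those
    that pass segregation and ENU-likeness and — when ``annotations`` is
    provided — carry a reported effect class.  Variants are matched
    between pools exactly on (chrom, pos, ref, alt).  SIFT scores are
    attached wherever the lookup has the key.  Both lists are sorted by
    position.
    """
    wt_by_key = {c.key: c for c in wt_calls}
    unfiltered: List[AnnotatedCandidate] = []
    filtered: List[AnnotatedCandidate] = []
    for call in mut_calls:
        if not interval.contains(call.chrom, call.pos):
            continue
        wt = wt_by_key.get(call.key)
        anns = tuple(annotations.get(call.key, ())) if annotations is not None else ()
        cand = AnnotatedCandidate(
            call=call,
            wt_ro=wt.ro if wt else None,
            wt_ao=wt.ao if wt else None,
            annotations=anns,
            sift=sift_lookup.get(call.key) if sift_lookup else None,
        )
        unfiltered.append(cand)
        if not segregates_with_phenotype(call, wt, thr):
            continue
        if not is_enu_like(call):
            continue
        if annotations is not None and cand.klass not in REPORTED_CLASSES:
            continue
        filtered.append(cand)
    keyfn = lambda c: (c.call.chrom, c.call.pos)
    unfiltered.sort(key=keyfn)
    filtered.sort(key=keyfn)
    return unfiltered, filtered


def count_candidate_genes(filtered: Sequence[AnnotatedCandidate]) -> int:
    """Distinct gene symbols among missense/nonsense/splicing candidates."""
    genes = set()
    for cand in filtered:
        ann = cand.best
        if ann and ann.gene and cand.klass in GENE_COUNT_CLASSES:
            genes.add(ann.gene)
    return len(genes)


def class_tally(filtered: Sequence[AnnotatedCandidate]) -> Dict[str, int]:
    """Per-class candidate counts plus the total.

    Each variant is counted once under its most severe class.  Keys:
    nonsynonymous, nonsense (stopgain), startloss, stoploss, splicing,
    total.
    """
    tally = {"nonsynonymous": 0, "nonsense": 0, "startloss": 0, "stoploss": 0, "splicing": 0, "total": 0}
    for cand in filtered:
        klass = cand.klass
        if klass == "stopgain":
            tally["nonsense"] += 1
        elif klass in tally:
            tally[klass] += 1
        else:
            continue
        tally["total"] += 1
    return tally
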