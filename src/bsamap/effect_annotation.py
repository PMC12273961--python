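"""Minimal gene-model-based consequence annotation.

Classifies each variant against every overlapping transcript into the
effect classes the candidate report uses (synonymous, nonsynonymous,
stopgain, stoploss, startloss, frameshift, nonframeshift) and region
classes (exonic, splicing, intronic, utr5, utr3, intergenic), with
c./p. notation rendered as ``exonNN: c.<ref><cdsPos><alt>: p.<aa><aaPos><aa|X>``.

Codon rebuilding splices the CDS from the exon structure (reverse
complemented for minus-strand models) and translates with the standard
nuclear code.  This is a deliberately small annotator: no HGVS
right-shifting, no UTR sub-classification, no canonical-transcript
ontology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .formats import GeneModel, VariantCall

log = logging.getLogger(__name__)

__all__ = ["EffectAnnotation", "annotate_variant", "severity_rank"]

REGIONS = ("exonic", "splicing", "intronic", "utr5", "utr3", "intergenic")
EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "startloss",
    "frameshift",
    "nonframeshift",
    "unknown",
)

# Total severity order used to pick a single class per variant.
_SEVERITY = {
    "stopgain": 10,
    "startloss": 9,
    "stoploss": 8,
    "splicing": 7,
    "nonsynonymous": 6,
    "frameshift": 5,
    "nonframeshift": 4,
    "synonymous": 3,
    "unknown": 2,
    "exonic": 2,
    "utr5": 1,
    "utr3": 1,
    "intronic": 1,
    "intergenic": 0,
}


@dataclass
class EffectAnnotation:
    """Consequence of one variant on one transcript."""

    region: str
    effect: Optional[str] = None  # populated only for exonic region
    gene: Optional[str] = None
    transcript: Optional[str] = None
    exon: Optional[int] = None  # 1-based in transcription order
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None

    @property
    def klass(self) -> str:
        """The single class label used for severity ranking and reports."""
        return self.effect if (self.region == "exonic" and self.effect) else self.region

    def notation(self) -> str:
        """``exonNN: c....: p....`` (pieces omitted when unknown)."""
        parts = []
        if self.exon is not None:
            parts.append(f"exon{self.exon}")
        if self.cdna_change:
            parts.append(self.cdna_change)
        if self.protein_change:
            parts.append(self.protein_change)
        return ": ".join(parts)


def severity_rank(effect_or_region: str) -> int:
    """Position of a class label in the total severity order (higher = worse)."""
    try:
        return _SEVERITY[effect_or_region]
    except KeyError:
        raise ValueError(f"unknown effect/region class {effect_or_region!r}") from None


def most_severe(annotations: Sequence[EffectAnnotation]) -> EffectAnnotation:
    return max(annotations, key=lambda a: severity_rank(a.klass))


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return "X" if aa == "*" else aa


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom][start - 1 : end]
    return str(seq).upper()


def annotate_variant(
    call: VariantCall,
    models: Sequence[GeneModel],
    genome: Mapping[str, object],
    splice_window: int = 2,
) -> List[EffectAnnotation]:
    """Annotate one variant against every overlapping transcript.

    Returns one :class:`EffectAnnotation` per overlapping model, or a
    single intergenic annotation if none overlap.  A reference mismatch
    against ``genome`` is warned about and annotation proceeds.
    """
    span = (call.pos, call.pos + len(call.ref) - 1)
    try:
        observed = _fetch(genome, call.chrom, *span)
        if observed != call.ref:
            log.warning(
                "reference mismatch at %s:%d: genome has %r, call has %r",
                call.chrom, call.pos, observed, call.ref,
            )
    except (KeyError, IndexError):
        raise ValueError(f"position {call.chrom}:{call.pos} is outside the genome sequence")

    hits = [m for m in models if m.chrom == call.chrom and not (span[1] < m.tx_start or span[0] > m.tx_end)]
    if not hits:
        return [EffectAnnotation(region="intergenic")]
    return [_annotate_one(call, m, genome, splice_window) for m in hits]


def _exon_number(model: GeneModel, genomic_index: int) -> int:
    return genomic_index + 1 if model.strand == "+" else len(model.exons) - genomic_index


def _annotate_one(
    call: VariantCall, model: GeneModel, genome: Mapping[str, object], splice_window: int
) -> EffectAnnotation:
    lo, hi = call.pos, call.pos + len(call.ref) - 1
    base = dict(gene=model.gene, transcript=model.transcript)

    exon_idx = None
    inside_exon = False
    for i, (s, e) in enumerate(model.exons):
        if lo >= s and hi <= e:
            exon_idx, inside_exon = i, True
            break
        if not (hi < s or lo > e):  # partial overlap: spans a splice boundary
            return EffectAnnotation(region="splicing", exon=_exon_number(model, i), **base)

    if not inside_exon:
        # fully intronic (or flanking): splicing if within splice_window of a boundary
        for i, (s, e) in enumerate(model.exons):
            if 0 < s - hi <= splice_window or 0 < lo - e <= splice_window:
                return EffectAnnotation(region="splicing", exon=_exon_number(model, i), **base)
        return EffectAnnotation(region="intronic", **base)

    exon_no = _exon_number(model, exon_idx)
    if not model.is_coding:
        return EffectAnnotation(region="exonic", effect="unknown", exon=exon_no, **base)

    if hi < model.cds_start or lo > model.cds_end:
        # UTR side depends on strand
        upstream = hi < model.cds_start
        region = ("utr5" if upstream else "utr3") if model.strand == "+" else ("utr3" if upstream else "utr5")
        return EffectAnnotation(region=region, exon=exon_no, **base)

    if call.is_indel:
        effect = "frameshift" if call.length_difference % 3 else "nonframeshift"
        cds_pos = _cds_position(model, max(lo, model.cds_start))
        cdna = f"c.{call.ref}{cds_pos}{call.alt}" if cds_pos else None
        return EffectAnnotation(region="exonic", effect=effect, exon=exon_no, cdna_change=cdna, **base)

    # same-length substitution (1 or more bp): evaluate per base, keep most severe codon change
    cds_seq = _spliced_cds(model, genome)
    candidates: List[EffectAnnotation] = []
    for offset in range(len(call.ref)):
        pos = call.pos + offset
        if pos < model.cds_start or pos > model.cds_end:
            continue
        cds_pos = _cds_position(model, pos)
        if cds_pos is None:
            continue
        ref_b, alt_b = call.ref[offset], call.alt[offset]
        if model.strand == "-":
            ref_b, alt_b = _revcomp(ref_b), _revcomp(alt_b)
        ann = _classify_substitution(cds_seq, cds_pos, ref_b, alt_b, exon_no, base)
        candidates.append(ann)
    if not candidates:
        return EffectAnnotation(region="exonic", effect="unknown", exon=exon_no, **base)
    # MNVs within one codon: rebuild the codon with all changed bases at once
    if len(call.ref) > 1:
        joint = _classify_mnv(call, model, cds_seq, exon_no, base)
        if joint is not None:
            return joint
    return most_severe(candidates)


def _classify_mnv(call, model, cds_seq, exon_no, base) -> Optional[EffectAnnotation]:
    """A same-length multi-base substitution confined to one codon."""
    cds_positions = []
    for offset in range(len(call.ref)):
        p = _cds_position(model, call.pos + offset)
        if p is None:
            return None
        cds_positions.append(p)
    codons = {(p - 1) // 3 for p in cds_positions}
    if len(codons) != 1:
        return None  # crosses a codon boundary: per-base decomposition applies
    codon_i = codons.pop()
    codon = list(cds_seq[3 * codon_i : 3 * codon_i + 3])
    ref_codon = "".join(codon)
    for offset, p in enumerate(cds_positions):
        ref_b, alt_b = call.ref[offset], call.alt[offset]
        if model.strand == "-":
            ref_b, alt_b = _revcomp(ref_b), _revcomp(alt_b)
        codon[(p - 1) % 3] = alt_b
    alt_codon = "".join(codon)
    first = min(cds_positions)
    ref_s = call.ref if model.strand == "+" else _revcomp(call.ref)
    alt_s = call.alt if model.strand == "+" else _revcomp(call.alt)
    return _codon_annotation(
        ref_codon, alt_codon, codon_i, f"c.{ref_s}{first}{alt_s}", exon_no, base
    )


def _classify_substitution(cds_seq, cds_pos, ref_b, alt_b, exon_no, base) -> EffectAnnotation:
    idx0 = cds_pos - 1
    codon_i = idx0 // 3
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    if len(codon) < 3:
        return EffectAnnotation(region="exonic", effect="unknown", exon=exon_no, **base)
    within = idx0 % 3
    if codon[within] != ref_b:
        log.warning("CDS/ref disagreement at cds position %d (%r vs %r)", cds_pos, codon[within], ref_b)
    alt_codon = codon[:within] + alt_b + codon[within + 1 :]
    return _codon_annotation(codon, alt_codon, codon_i, f"c.{ref_b}{cds_pos}{alt_b}", exon_no, base)


def _codon_annotation(ref_codon, alt_codon, codon_i, cdna, exon_no, base) -> EffectAnnotation:
    ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        effect = "startloss"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "X":
        effect = "stopgain"
    elif ref_aa == "X":
        effect = "stoploss"
    else:
        effect = "nonsynonymous"
    return EffectAnnotation(
        region="exonic",
        effect=effect,
        exon=exon_no,
        cdna_change=cdna,
        protein_change=f"p.{ref_aa}{codon_i + 1}{alt_aa}",
        **base,
    )


def _spliced_cds(model: GeneModel, genome: Mapping[str, object]) -> str:
    """Sense-strand CDS sequence assembled from the exon structure."""
    parts = [_fetch(genome, model.chrom, s, e) for s, e in model.cds_segments()]
    seq = "".join(parts)
    return _revcomp(seq) if model.strand == "-" else seq


def _cds_position(model: GeneModel, pos: int) -> Optional[int]:
    """1-based position of a genomic coordinate within the spliced CDS."""
    offset = 0
    for s, e in model.cds_segments():
        if s <= pos <= e:
            g = offset + (pos - s)  # 0-based index in genomic-order concatenation
            total = model.cds_length()
            return g + 1 if model.strand == "+" else total - g
        offset += e - s + 1
    return None
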