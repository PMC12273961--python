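"""Consequence classification against toy gene models and an independent oracle."""

import numpy as np
import pytest

from bsamap.effect_annotation import annotate_variant, most_severe, severity_rank
from bsamap.formats import GeneModel, VariantCall

from conftest import revcomp

# independent hand-walked codon table (standard nuclear code)
_T = {}
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for i, b1 in enumerate("TCAG"):
    for j, b2 in enumerate("TCAG"):
        for k, b3 in enumerate("TCAG"):
            _T[b1 + b2 + b3] = _AAS[16 * i + 4 * j + k]


def oracle_translate(codon):
    aa = _T[codon]
    return "X" if aa == "*" else aa


def call(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, 0, 10)


class TestToyFixture:
    """Single-exon gene on chrT: exon 1..30, CDS 11..22 = ATG AAA TGC TAA."""

    def test_stopgain(self, toy_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 19, "C", "A"), [toy_gene], toy_genome)
        assert (ann.region, ann.effect, ann.exon) == ("exonic", "stopgain", 1)
        assert ann.cdna_change == "c.C9A"
        assert ann.protein_change == "p.C3X"
        assert ann.notation() == "exon1: c.C9A: p.C3X"

    def test_synonymous(self, toy_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 16, "A", "G"), [toy_gene], toy_genome)
        assert ann.effect == "synonymous"
        assert ann.protein_change == "p.K2K"

    def test_startloss(self, toy_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 11, "A", "G"), [toy_gene], toy_genome)
        assert ann.effect == "startloss"

    def test_stoploss(self, toy_gene, toy_genome):
        # TAA -> CAA (Q): position 20 is the first base of the stop codon
        (ann,) = annotate_variant(call("chrT", 20, "T", "C"), [toy_gene], toy_genome)
        assert ann.effect == "stoploss"

    def test_nonsynonymous(self, toy_gene, toy_genome):
        # AAA (K) -> ACA (T) at cds pos 5
        (ann,) = annotate_variant(call("chrT", 15, "A", "C"), [toy_gene], toy_genome)
        assert ann.effect == "nonsynonymous"
        assert ann.protein_change == "p.K2T"

    def test_utr_regions(self, toy_gene, toy_genome):
        (ann5,) = annotate_variant(call("chrT", 5, "C", "A"), [toy_gene], toy_genome)
        (ann3,) = annotate_variant(call("chrT", 25, "G", "A"), [toy_gene], toy_genome)
        assert (ann5.region, ann3.region) == ("utr5", "utr3")

    def test_intergenic(self, toy_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 40, "T", "A"), [toy_gene], toy_genome)
        assert ann.region == "intergenic"

    def test_frameshift_and_nonframeshift(self, toy_gene, toy_genome):
        (fs,) = annotate_variant(call("chrT", 15, "AA", "A"), [toy_gene], toy_genome)
        assert fs.effect == "frameshift"
        (nf,) = annotate_variant(call("chrT", 14, "AAAT", "A"), [toy_gene], toy_genome)
        assert nf.effect == "nonframeshift"


class TestStrandSymmetry:
    def test_minus_strand_matches_mirrored_plus(self, toy_gene, toy_gene_minus, toy_genome):
        for pos, ref, alt in [(19, "C", "A"), (16, "A", "G"), (11, "A", "G"), (15, "A", "C")]:
            (plus,) = annotate_variant(call("chrT", pos, ref, alt), [toy_gene], toy_genome)
            mpos = 61 - pos
            (minus,) = annotate_variant(
                call("chrM", mpos, revcomp(ref), revcomp(alt)), [toy_gene_minus], toy_genome
            )
            assert minus.effect == plus.effect
            assert minus.cdna_change == plus.cdna_change
            assert minus.protein_change == plus.protein_change
            assert minus.exon == plus.exon


class TestSplicing:
    def test_intronic_within_splice_window(self, two_exon_gene, toy_genome):
        # exon1 ends at 10: positions 11 and 12 are donor-side splice region
        for pos in (11, 12):
            ref = toy_genome["chrT"][pos - 1]
            alt = "G" if ref != "G" else "C"
            (ann,) = annotate_variant(call("chrT", pos, ref, alt), [two_exon_gene], toy_genome)
            assert ann.region == "splicing", pos

    def test_deep_intron_is_intronic(self, two_exon_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 15, "A", "C"), [two_exon_gene], toy_genome)
        assert ann.region == "intronic"

    def test_acceptor_side_window(self, two_exon_gene, toy_genome):
        # exon2 starts at 21: 19 and 20 are acceptor-side splice region
        (ann,) = annotate_variant(call("chrT", 19, "C", "A"), [two_exon_gene], toy_genome)
        assert ann.region == "splicing"

    def test_variant_spanning_exon_boundary(self, two_exon_gene, toy_genome):
        (ann,) = annotate_variant(call("chrT", 10, "CA", "C"), [two_exon_gene], toy_genome)
        assert ann.region == "splicing"


class TestSeverity:
    def test_order(self):
        assert severity_rank("stopgain") > severity_rank("nonsynonymous")
        assert severity_rank("splicing") > severity_rank("synonymous")
        assert severity_rank("startloss") > severity_rank("stoploss")
        assert severity_rank("nonsynonymous") > severity_rank("frameshift")

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError):
            severity_rank("benign")


def random_coding_gene(rng, n_exons=2):
    """A random multi-exon coding model on a random sequence, plus the sequence."""
    n_codons = int(rng.integers(4, 20))
    cds = "ATG" + "".join(
        rng.choice([c for c in _T if _T[c] != "*"]) for _ in range(n_codons - 2)
    ) + str(rng.choice(["TAA", "TAG", "TGA"]))
    # split the CDS across exons with random intron gaps
    cut = sorted(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    pieces, prev = [], 0
    for c in list(cut) + [len(cds)]:
        pieces.append(cds[prev:c])
        prev = c
    seq, exons, pos = "", [], 1
    utr5 = "".join(rng.choice(list("ACGT"), size=5))
    seq += utr5
    first_exon_start = 1
    cds_start = len(seq) + 1
    for i, piece in enumerate(pieces):
        exon_start = len(seq) + 1
        seq += piece
        exons.append([exon_start, len(seq)])
        if i < len(pieces) - 1:
            seq += "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 15))))
    cds_end = len(seq)
    utr3 = "".join(rng.choice(list("ACGT"), size=5))
    seq += utr3
    exons[0][0] = first_exon_start  # extend first exon through the 5' UTR
    exons[-1][1] = len(seq)  # and last exon through the 3' UTR
    model = GeneModel("rnd", "rnd.t1", "chrR", "+", [tuple(e) for e in exons], cds_start, cds_end)
    return model, seq, cds, cds_start


class TestRandomCdsOracle:
    def test_classification_matches_hand_translation(self):
        """Codon rebuild + classification vs an exon-walk + codon-table oracle."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(60):
            model, seq, cds, cds_start = random_coding_gene(rng, n_exons=int(rng.integers(1, 4)))
            genome = {"chrR": seq}
            # walk the CDS: genomic position of each spliced-CDS offset
            cds_positions = [p for s, e in model.cds_segments() for p in range(s, e + 1)]
            for _ in range(10):
                k = int(rng.integers(0, len(cds)))
                gpos = cds_positions[k]
                ref_b = cds[k]
                alt_b = str(rng.choice([b for b in "ACGT" if b != ref_b]))
                (ann,) = annotate_variant(
                    VariantCall("chrR", gpos, ref_b, alt_b, 0, 9), [model], genome
                )
                codon_i, within = divmod(k, 3)
                ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
                alt_codon = ref_codon[:within] + alt_b + ref_codon[within + 1 :]
                ref_aa, alt_aa = oracle_translate(ref_codon), oracle_translate(alt_codon)
                if codon_i == 0 and alt_codon != "ATG":
                    expect = "startloss"
                elif ref_aa == alt_aa:
                    expect = "synonymous"
                elif alt_aa == "X":
                    expect = "stopgain"
                elif ref_aa == "X":
                    expect = "stoploss"
                else:
                    expect = "nonsynonymous"
                assert ann.effect == expect, (seq, gpos, ref_b, alt_b)
                assert ann.cdna_change == f"c.{ref_b}{k + 1}{alt_b}"
                assert ann.protein_change == f"p.{ref_aa}{codon_i + 1}{alt_aa}"
                checked += 1
        assert checked >= 500

    def test_synonymous_iff_identical_translation(self):
        rng = np.random.default_rng(7)
        model, seq, cds, _ = random_coding_gene(rng, n_exons=1)
        genome = {"chrR": seq}
        cds_positions = [p for s, e in model.cds_segments() for p in range(s, e + 1)]
        for k in range(len(cds)):
            for alt_b in "ACGT":
                if alt_b == cds[k]:
                    continue
                (ann,) = annotate_variant(
                    VariantCall("chrR", cds_positions[k], cds[k], alt_b, 0, 9), [model], genome
                )
                codon_i, within = divmod(k, 3)
                ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
                alt_codon = ref_codon[:within] + alt_b + ref_codon[within + 1 :]
                same = oracle_translate(ref_codon) == oracle_translate(alt_codon)
                assert (ann.effect == "synonymous") == same


class TestMnv:
    def test_two_base_substitution_same_codon(self, toy_gene, toy_genome):
        # AAA (K) -> GCA (A): cds positions 4-5 in codon 2
        (ann,) = annotate_variant(call("chrT", 14, "AA", "GC"), [toy_gene], toy_genome)
        assert ann.effect == "nonsynonymous"
        assert ann.cdna_change == "c.AA4GC"

    def test_two_base_substitution_across_codons_most_severe(self, toy_gene, toy_genome):
        # cds positions 6|7 span codons 2 and 3: AAA->AAT (syn? K->N) and TGC->GGC
        (ann,) = annotate_variant(call("chrT", 16, "AT", "TG"), [toy_gene], toy_genome)
        assert ann.region == "exonic"
        # decomposed per codon; most severe of the two single-codon changes
        assert ann.effect in {"nonsynonymous", "stopgain", "stoploss"}

    def test_most_severe_across_transcripts(self, toy_gene, toy_genome):
        other = GeneModel("toy2", "toy2.t1", "chrT", "+", [(1, 30)], None, None)
        anns = annotate_variant(call("chrT", 19, "C", "A"), [toy_gene, other], toy_genome)
        assert len(anns) == 2
        assert most_severe(anns).effect == "stopgain"
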