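import numpy as np
import pytest

from bsamap.formats import GeneModel, GenomeIndex, VariantCall
from bsamap.simulate import SimConfig, simulate_cross, simulate_reads

# --- toy annotation fixtures -------------------------------------------------
# chrT: 60 bp, forward gene with single exon 1..30, CDS 11..22 = ATG AAA TGC TAA
CHRT_SEQ = "CCCCCCCCCC" + "ATGAAATGCTAA" + "GGGGGGGG" + "T" * 30
assert len(CHRT_SEQ) == 60
assert CHRT_SEQ[10:22] == "ATGAAATGCTAA"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@pytest.fixture
def toy_genome():
    # chrM is the mirror image of chrT, for strand-symmetry checks
    return {"chrT": CHRT_SEQ, "chrM": revcomp(CHRT_SEQ)}


@pytest.fixture
def toy_gene():
    return GeneModel("toy", "toy.t1", "chrT", "+", [(1, 30)], 11, 22)


@pytest.fixture
def toy_gene_minus():
    # mirror of toy_gene on chrM (length 60): span x -> 61 - x
    return GeneModel("toym", "toym.t1", "chrM", "-", [(31, 60)], 39, 50)


@pytest.fixture
def two_exon_gene():
    # exons 1..10 and 21..30, CDS 5..26: spliced CDS = 6 + 6 = 12 bases
    return GeneModel("two", "two.t1", "chrT", "+", [(1, 10), (21, 30)], 5, 26)


def vc(chrom="chr1", pos=100, ref="C", alt="A", ro=0, ao=10, qual=None):
    return VariantCall(chrom, pos, ref, alt, ro, ao, qual)


@pytest.fixture
def make_call():
    return vc


# --- simulated cross (module-scoped: several tests share one run) ------------

SMALL_SIM = SimConfig(
    chrom_lengths=(("chr1", 8_000_000), ("chr2", 8_000_000)),
    causative_pos=4_000_000,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cross():
    rng = np.random.default_rng(SMALL_SIM.seed)
    cross = simulate_cross(SMALL_SIM, rng)
    mut, wt = simulate_reads(cross, rng)
    return cross, mut, wt


@pytest.fixture
def genome_index():
    return GenomeIndex([("chr1", 8_000_000), ("chr2", 8_000_000)])
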