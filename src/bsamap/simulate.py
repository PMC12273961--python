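"""Synthetic F2-incross generator with known ground truth.

Emulates the statistical structure the mapping assumes: heterozygous
carrier parents are incrossed; phenotypically mutant offspring are
homozygous for the causative allele and, by linkage, for the founder
haplotype around it, while wild-type siblings stay heterozygous there.

Model
-----
* Background polymorphism: strain-level het SNP/indel sites at a
  configurable density; every founder haplotype carries the alternate
  allele independently with probability 1/2.
* The causative substitution sits on one mutagenized founder haplotype
  whose pattern is identical by descent across all carrier parents on
  the causative chromosome; this is what produces mutant-pool
  homozygosity at the locus.
* Meiosis: crossovers form a Poisson process along the chromosome at
  1 Morgan per 100 x mb_per_cM megabases (Haldane model, no
  interference), so the recombination probability between loci d Mb
  apart is r = (1 - exp(-2 d / (100 mb_per_cM))) / 2.
* Clutches are independent parent pairs; pools are built per clutch
  quota and the pool allele fraction at each site is the mean over
  pooled chromosomes.
* Read sampling: per site and pool, depth ~ Poisson(coverage) and
  AO ~ Binomial(depth, pool alt fraction); sites with AO = 0 are
  omitted from that pool's VCF, as a variant caller would not report
  them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .formats import GenomeIndex, VariantCall, write_fai
from .recomb import HET, HOM_MUT, UNKNOWN, MarkerGenotypeTable, write_genotype_table

__all__ = [
    "SimConfig",
    "SiteSet",
    "TruthRecord",
    "CrossResult",
    "simulate_cross",
    "simulate_reads",
    "mutant_marker_genotypes",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated cross.

    Defaults mirror a three-clutch, 30-animal-per-pool zebrafish incross
    sequenced at 30X on a two-chromosome 2 x 25 Mb toy genome with
    300 het SNPs and 50 het indels per Mb of background polymorphism.
    """

    chrom_lengths: Tuple[Tuple[str, int], ...] = (("chr1", 25_000_000), ("chr2", 25_000_000))
    snp_per_mb: float = 300.0
    indel_per_mb: float = 50.0
    causative_chrom: str = "chr1"
    causative_pos: int = 12_000_000
    n_clutches: int = 3
    animals_per_clutch: int = 10
    coverage: float = 30.0
    mb_per_cm: float = 0.74
    extra_mutation_per_mb: float = 0.0  # incidental induced mutations, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snp_per_mb < 0 or self.indel_per_mb < 0 or self.extra_mutation_per_mb < 0:
            raise ValueError("densities must be >= 0")
        if self.n_clutches < 1 or self.animals_per_clutch < 1:
            raise ValueError("pool design must have >= 1 clutch and >= 1 animal per clutch")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        lengths = dict(self.chrom_lengths)
        if self.causative_chrom not in lengths:
            raise ValueError(f"causative chromosome {self.causative_chrom} not in genome")
        if not 1 <= self.causative_pos <= lengths[self.causative_chrom]:
            raise ValueError("causative position outside its chromosome")

    @property
    def pool_size(self) -> int:
        return self.n_clutches * self.animals_per_clutch

    def genome_index(self) -> GenomeIndex:
        return GenomeIndex(list(self.chrom_lengths))


@dataclass
class SiteSet:
    """Polymorphic sites of one chromosome, sorted by position."""

    positions: np.ndarray  # 1-based, strictly increasing
    ref: List[str]
    alt: List[str]
    is_indel: np.ndarray  # bool
    is_extra: np.ndarray  # incidental single-haplotype mutations

    @property
    def n(self) -> int:
        return int(self.positions.size)


@dataclass
class TruthRecord:
    """Ground truth of one simulated cross."""

    causative_chrom: str
    causative_pos: int
    causative_ref: str
    causative_alt: str
    # per chrom: (positions, mutant-pool alt fraction, wt-pool alt fraction)
    fractions: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]


@dataclass
class CrossResult:
    cfg: SimConfig
    sites: Dict[str, SiteSet]
    truth: TruthRecord
    # founder (mutagenized) haplotype pattern on the causative chromosome
    founder_hap: np.ndarray
    # per mutant animal, per chrom: (allele array hap A, allele array hap B)
    mutant_animals: List[Dict[str, Tuple[np.ndarray, np.ndarray]]]


def _make_sites(cfg: SimConfig, rng: np.random.Generator) -> Dict[str, SiteSet]:
    sites: Dict[str, SiteSet] = {}
    for chrom, length in cfg.chrom_lengths:
        mb = length / 1e6
        n_snp = int(round(cfg.snp_per_mb * mb))
        n_indel = int(round(cfg.indel_per_mb * mb))
        n_extra = int(round(cfg.extra_mutation_per_mb * mb))
        n_total = n_snp + n_indel + n_extra
        pos = np.unique(rng.integers(1, length + 1, size=n_total))
        pos = pos[pos != cfg.causative_pos] if chrom == cfg.causative_chrom else pos
        n = pos.size
        # partition positions into classes proportionally
        kinds = rng.permutation(
            np.concatenate([
                np.zeros(min(n_snp, n), dtype=np.int8),
                np.ones(max(min(n_indel, n - min(n_snp, n)), 0), dtype=np.int8),
                2 * np.ones(max(n - n_snp - n_indel, 0), dtype=np.int8),
            ])[:n]
        )
        is_indel = kinds == 1
        is_extra = kinds == 2
        ref: List[str] = []
        alt: List[str] = []
        base_idx = rng.integers(0, 4, size=n)
        for i in range(n):
            b = chr(_BASES[base_idx[i]][0])
            if is_indel[i]:
                d = int(rng.integers(1, 11))
                tail = "".join(chr(_BASES[j][0]) for j in rng.integers(0, 4, size=d))
                if rng.random() < 0.5:
                    ref.append(b + tail)  # deletion
                    alt.append(b)
                else:
                    ref.append(b)  # insertion
                    alt.append(b + tail)
            else:
                a = chr(_BASES[(base_idx[i] + int(rng.integers(1, 4))) % 4][0])
                ref.append(b)
                alt.append(a)

        if chrom == cfg.causative_chrom:
            # splice in the causative substitution
            ci = int(np.searchsorted(pos, cfg.causative_pos))
            pos = np.insert(pos, ci, cfg.causative_pos)
            rb = chr(_BASES[int(rng.integers(0, 4))][0])
            ab = chr(_BASES[(_BASES.tolist().index(rb.encode()) + int(rng.integers(1, 4))) % 4][0])
            ref.insert(ci, rb)
            alt.insert(ci, ab)
            is_indel = np.insert(is_indel, ci, False)
            is_extra = np.insert(is_extra, ci, False)
        sites[chrom] = SiteSet(pos, ref, alt, is_indel, is_extra)
    return sites


def _gamete(
    haps: Tuple[np.ndarray, np.ndarray],
    positions: np.ndarray,
    length: int,
    morgans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: Poisson crossovers, no interference."""
    n_x = rng.poisson(morgans)
    start = int(rng.integers(0, 2))
    if n_x == 0:
        return haps[start].copy()
    xpos = np.sort(rng.integers(1, length + 1, size=n_x))
    phase = (start + np.searchsorted(xpos, positions, side="left")) % 2
    return np.where(phase == 0, haps[0], haps[1])


def _carrier_haplotype(
    founder: np.ndarray,
    background: np.ndarray,
    positions: np.ndarray,
    length: int,
    morgans: float,
    ci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """A once-recombined copy of the founder haplotype, conditioned on
    retaining the causative allele (accept/reject on the meiotic product)."""
    background = background.copy()
    background[ci] = False  # only the founder haplotype carries the causative allele
    for _ in range(64):
        hap = _gamete((founder, background), positions, length, morgans, rng)
        if hap[ci]:
            return hap
    hap = founder.copy()  # vanishing-probability fallback
    return hap


def simulate_cross(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> CrossResult:
    """Run the cross and return ground-truth pool allele fractions.

    Byte-identical output for a fixed ``cfg.seed`` (when ``rng`` is not
    supplied).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sites = _make_sites(cfg, rng)
    lengths = dict(cfg.chrom_lengths)
    cchrom = cfg.causative_chrom
    csites = sites[cchrom]
    ci = int(np.searchsorted(csites.positions, cfg.causative_pos))

    founder = rng.random(csites.n) < 0.5
    founder[csites.is_extra] = False
    founder[ci] = True  # the causative allele rides the mutagenized haplotype

    # incidental induced mutations: each lives on one random non-founder haplotype
    extra_assign: Dict[Tuple[str, int], Tuple[int, int]] = {}
    for chrom, ss in sites.items():
        for idx in np.flatnonzero(ss.is_extra):
            extra_assign[(chrom, int(idx))] = (int(rng.integers(cfg.n_clutches)), int(rng.integers(4)))

    f_sum_mut = {c: np.zeros(s.n) for c, s in sites.items()}
    f_sum_wt = {c: np.zeros(s.n) for c, s in sites.items()}
    mutant_animals: List[Dict[str, Tuple[np.ndarray, np.ndarray]]] = []

    for clutch in range(cfg.n_clutches):
        haps: Dict[str, np.ndarray] = {}
        for chrom, ss in sites.items():
            h = rng.random((4, ss.n)) < 0.5
            h[:, ss.is_extra] = False
            if chrom == cchrom:
                # Each carrier parent inherits the mutagenized founder
                # haplotype through one further meiosis (founder -> F1 ->
                # carrier), so the identical-by-descent segment around the
                # locus is truncated independently per parent.
                length = lengths[chrom]
                morgans = (length / 1e6) / (100.0 * cfg.mb_per_cm)
                h[0] = _carrier_haplotype(founder, h[0], ss.positions, length, morgans, ci, rng)
                h[2] = _carrier_haplotype(founder, h[2], ss.positions, length, morgans, ci, rng)
                h[1, ci] = h[3, ci] = False
            haps[chrom] = h
        for (echrom, eidx), (eclutch, erow) in extra_assign.items():
            if eclutch == clutch:
                haps[echrom][erow, eidx] = True

        need_mut = need_wt = cfg.animals_per_clutch
        guard = 0
        while (need_mut or need_wt) and guard < 100_000:
            guard += 1
            child: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            for chrom, ss in sites.items():
                length = lengths[chrom]
                morgans = (length / 1e6) / (100.0 * cfg.mb_per_cm)
                a = _gamete((haps[chrom][0], haps[chrom][1]), ss.positions, length, morgans, rng)
                b = _gamete((haps[chrom][2], haps[chrom][3]), ss.positions, length, morgans, rng)
                child[chrom] = (a, b)
            is_mutant = bool(child[cchrom][0][ci] and child[cchrom][1][ci])
            if is_mutant and need_mut:
                need_mut -= 1
                mutant_animals.append(child)
                for chrom in sites:
                    f_sum_mut[chrom] += child[chrom][0].astype(np.int64) + child[chrom][1].astype(np.int64)
            elif not is_mutant and need_wt:
                need_wt -= 1
                for chrom in sites:
                    f_sum_wt[chrom] += child[chrom][0].astype(np.int64) + child[chrom][1].astype(np.int64)
        if need_mut or need_wt:
            raise RuntimeError("offspring quota not reached; check the cross configuration")

    denom = 2.0 * cfg.pool_size
    fractions = {
        c: (sites[c].positions.copy(), f_sum_mut[c] / denom, f_sum_wt[c] / denom) for c in sites
    }
    truth = TruthRecord(cchrom, cfg.causative_pos, csites.ref[ci], csites.alt[ci], fractions)
    return CrossResult(cfg, sites, truth, founder, mutant_animals)


def simulate_reads(
    cross: CrossResult,
    rng: np.random.Generator,
    coverage: Optional[float] = None,
) -> Tuple[List[VariantCall], List[VariantCall]]:
    """Sample pooled-sequencing read counts from the true pool fractions.

    Returns (mutant calls, wild-type calls), each sorted by (chrom, pos),
    containing only sites where at least one alternate read was drawn.
    """
    cov = coverage if coverage is not None else cross.cfg.coverage
    out: Tuple[List[VariantCall], List[VariantCall]] = ([], [])
    for chrom in [c for c, _ in cross.cfg.chrom_lengths]:
        positions, f_mut, f_wt = cross.truth.fractions[chrom]
        ss = cross.sites[chrom]
        for calls, frac in zip(out, (f_mut, f_wt)):
            depth = rng.poisson(cov, size=positions.size)
            ao = rng.binomial(depth, frac)
            ro = depth - ao
            for idx in np.flatnonzero(ao > 0):
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=int(positions[idx]),
                        ref=ss.ref[idx],
                        alt=ss.alt[idx],
                        ro=int(ro[idx]),
                        ao=int(ao[idx]),
                        qual=50.0,
                    )
                )
    return out


def mutant_marker_genotypes(cross: CrossResult, min_len_diff: int = 4) -> MarkerGenotypeTable:
    """Per-animal genotypes of the pooled mutants at causative-chromosome indels.

    Genotype is scored against the mutagenized founder haplotype's allele
    (the mutation-linked allele): homozygous for it -> hom_mut, one copy
    -> het, homozygous for the other allele -> unknown (a gel score of
    '?', as a double recombinant cannot be oriented).
    """
    cchrom = cross.cfg.causative_chrom
    ss = cross.sites[cchrom]
    lendiff = np.array([abs(len(r) - len(a)) for r, a in zip(ss.ref, ss.alt)])
    keep = np.flatnonzero(ss.is_indel & (lendiff >= min_len_diff))
    positions = [int(ss.positions[i]) for i in keep]
    animals = [f"animal{i + 1}" for i in range(len(cross.mutant_animals))]
    genotypes: Dict[str, List[str]] = {}
    for name, child in zip(animals, cross.mutant_animals):
        a, b = child[cchrom]
        row = []
        for i in keep:
            fa = cross.founder_hap[i]
            matches = int(a[i] == fa) + int(b[i] == fa)
            row.append({2: HOM_MUT, 1: HET, 0: UNKNOWN}[matches])
        genotypes[name] = row
    return MarkerGenotypeTable(cchrom, positions, animals, genotypes)


# ---------------------------------------------------------------------------
# output


def _write_vcf(path, calls: Sequence[VariantCall], genome: GenomeIndex) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap-simulate\n")
        for name, length in genome.entries:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">\n')
        fh.write('##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            qual = f"{c.qual:g}" if c.qual is not None else "."
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t.\tRO={c.ro};AO={c.ao}\n")


def generate_genome(cross: CrossResult, rng: Optional[np.random.Generator] = None) -> Dict[str, str]:
    """Random reference sequence consistent with every site's ref allele."""
    if rng is None:
        rng = np.random.default_rng(cross.cfg.seed + 997)
    genome: Dict[str, str] = {}
    for chrom, length in cross.cfg.chrom_lengths:
        seq = _BASES[rng.integers(0, 4, size=length)].copy()
        ss = cross.sites[chrom]
        for pos, ref in zip(ss.positions, ss.ref):
            end = min(pos - 1 + len(ref), length)
            seq[pos - 1 : end] = np.frombuffer(ref[: end - (pos - 1)].encode(), dtype="S1")
        genome[chrom] = seq.tobytes().decode()
    return genome


def write_simulation(
    cross: CrossResult,
    reads: Tuple[Sequence[VariantCall], Sequence[VariantCall]],
    out_dir: str | os.PathLike,
    write_genome: bool = False,
    per_animal: bool = False,
    min_len_diff: int = 4,
) -> Dict[str, str]:
    """Write mut.vcf, wt.vcf, truth.tsv, genome.fa.fai (and optional extras).

    Returns a dict of logical name -> path.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome = cross.cfg.genome_index()
    paths = {
        "mut_vcf": os.path.join(out_dir, "mut.vcf"),
        "wt_vcf": os.path.join(out_dir, "wt.vcf"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "fai": os.path.join(out_dir, "genome.fa.fai"),
    }
    mut_calls, wt_calls = reads
    _write_vcf(paths["mut_vcf"], mut_calls, genome)
    _write_vcf(paths["wt_vcf"], wt_calls, genome)
    write_fai(genome, paths["fai"])
    t = cross.truth
    with open(paths["truth"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tf_mut\tf_wt\tcausative\n")
        for chrom in [c for c, _ in cross.cfg.chrom_lengths]:
            positions, f_mut, f_wt = t.fractions[chrom]
            ss = cross.sites[chrom]
            for i in range(positions.size):
                is_c = int(chrom == t.causative_chrom and positions[i] == t.causative_pos)
                fh.write(
                    f"{chrom}\t{positions[i]}\t{ss.ref[i]}\t{ss.alt[i]}"
                    f"\t{f_mut[i]:.6f}\t{f_wt[i]:.6f}\t{is_c}\n"
                )
    if write_genome:
        paths["fasta"] = os.path.join(out_dir, "genome.fa")
        seqs = generate_genome(cross)
        with open(paths["fasta"], "w") as fh:
            for chrom, _ in cross.cfg.chrom_lengths:
                fh.write(f">{chrom}\n")
                s = seqs[chrom]
                for i in range(0, len(s), 60):
                    fh.write(s[i : i + 60] + "\n")
    if per_animal:
        paths["genotypes"] = os.path.join(out_dir, "mutant_genotypes.tsv")
        write_genotype_table(mutant_marker_genotypes(cross, min_len_diff), paths["genotypes"])
    return paths
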