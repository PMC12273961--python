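# Methods

## The mapping model

An F2 incross of heterozygous carriers produces phenotypically mutant
F3 offspring that are homozygous for the causative allele and — because
every carrier chromosome descends from one mutagenized founder
haplotype — homozygous for that haplotype's alleles in the linked
region. Phenotypically wild-type siblings (⅓ +/+, ⅔ +/−) remain
heterozygous there. The pipeline therefore contrasts *windowed
heterozygosity* between the two pools rather than raw allele
frequencies: a variant site is a **heterozygous point** when both
alleles are read-supported (`min(RO, AO) ≥ 2` by default) at a balanced
ratio (`RO/AO ∈ [0.25, 4]`, inclusive). Counting heterozygous points in
tiled windows gives `Het_mut(C)` and `Het_wt(C)` at window centers C,
and

    SNP_index(C) = (Het_wt(C) − Het_mut(C)) / (2 + Het_mut(C)).

The `+2` in the denominator regularises empty mutant windows (the index
is bounded below by −1 and above by `Het_wt/2`) and deliberately
asymmetrises the statistic: heterozygosity *loss* in the mutant pool is
amplified relative to heterozygosity excess. A side effect worth
knowing: on a homogeneous background the index has a small positive
mean (Jensen's inequality applied to the denominator), so the smoothed
track's zero crossings sit where the signal genuinely dies, not at the
noise floor.

Window counts are smoothed with a truncated moving average (mean over
centers within ± half the filter width; no zero padding, so chromosome
ends are not dragged negative). The interval is selected around the
genome-wide smoothed maximum, walking outward to the first non-positive
center on each side; the bound is placed midway between that center and
its interval-side neighbour, or at the chromosome end if the walk runs
off the track. Ties at the maximum break deterministically (chromosome
name, then coordinate).

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| window width / step | 10,000 / 10,000 | bp | tiling windows; heterozygous points partition cleanly |
| moving-average width | 750,000 | bp | ≈1 cM in zebrafish; the linkage scale of the signal |
| het point: min reads per allele | 2 | reads | one read is indistinguishable from sequencing error |
| het point: RO/AO bounds | [0.25, 4] | — | a real het site at ≥4-fold allele imbalance is unlikely at pool scale |
| min chromosome length | 1,000,000 | bp | drops unplaced scaffolds from mapping |
| segregation: mutant RO cap / AO floor | <2 / ≥2 | reads | mutant pool is fixed for the causative allele |
| segregation: wild-type RO/AO | (1, 4) strict | — | expected ratio 2 at the causative site (alt fraction ⅓) |
| marker min length difference | 4 | bp | conservative gel-resolvable product-size shift; configurable to 1 |
| splice window | 2 | bp | donor/acceptor dinucleotide convention |
| map density | 0.74 | Mb/cM | zebrafish genetic map |

## Effect annotation

A deliberately small, gene-model-driven annotator: region classes
(exonic, splicing, intronic, utr5/utr3, intergenic) from the transcript
structure; for exonic substitutions the affected codon is rebuilt from
the spliced CDS (reverse-complemented on − strand), translated with the
standard nuclear code, and classified as synonymous / nonsynonymous /
stopgain / stoploss / startloss; CDS indels are frameshift or
nonframeshift by length difference mod 3. Multi-transcript hits are
reported once under the most severe class (stopgain > startloss >
stoploss > splicing > nonsynonymous > frameshift > nonframeshift >
synonymous); 2-bp substitutions crossing a codon boundary are
decomposed per codon and the most severe change reported. There is no
HGVS right-shifting, no UTR sub-classification, and no canonical
transcript ontology. Models whose CDS length is not a multiple of 3 are
skipped with a warning at read time.

## Recombinant-mapping arithmetic

Recombination frequency at a marker is the fraction of genotyped mutant
animals scored heterozygous; distance is `Rf × 100 cM × 0.74 Mb/cM`
with no map-function correction (distances are small and the raw
product matches gel-based practice). Refinement uses the run structure
of heterozygous markers per animal: a het run anchored at the left
(right) end of the marker order excludes everything from the interval
edge through the run's innermost marker, inclusive of the marker's own
position; het markers strictly between homozygous ones imply a double
crossover and flag the animal as conflicting (excluded with a report
rather than an error — gels mis-call). An animal heterozygous at
*every* genotyped marker is directionally ambiguous; it is oriented
consistently with the unambiguous exclusions (the orientation keeping
the interval nonempty; if both work, the smaller exclusion, ties to the
left). Unknown genotypes flanked by identical known genotypes can
optionally be filled in (`--infer-missing`), never touching a known
score. The locus position estimate averages marker ± distance, choosing
the sign landing inside (or nearest) the refined interval, and reports
the sample standard deviation (n − 1; zero with a flag for a single
marker).

## The synthetic cross

The simulator emulates the statistical structure the mapping assumes,
not sequencing itself:

* **Background polymorphism** — strain-level het sites at 300 SNPs and
  50 indels per Mb; each founder haplotype carries the alternate allele
  independently with probability ½. Indel length differences are
  uniform on 1–10 bp.
* **The causative substitution** — rides one mutagenized founder
  haplotype that is identical by descent across all carrier parents.
  Each carrier parent's copy passes through one extra meiosis
  (founder → F1 → F2 carrier), so the IBD segment is truncated
  independently per parent; mutant offspring then add one more meiosis.
* **Meiosis** — crossovers are a Poisson process at 1 Morgan per 74 Mb
  (Haldane, no interference), giving recombination probability
  r = (1 − e^(−2d/74 Mb))/2 between loci d apart. The per-chromosome
  founder-allele agreement in the mutant pool follows
  (1 + (1 − r)²)/2, which the test suite checks against simulation.
* **Pools** — 3 clutches (independent parent pairs) × 10 animals per
  phenotype pool by default, mirroring common screen bulk designs.
  The mutant pool's alternate-allele fraction at the causative site is
  exactly 1; the wild-type sibling pool's is ≈⅓.
* **Reads** — per site and pool, depth ~ Poisson(coverage = 30 by
  default) and AO ~ Binomial(depth, pool fraction); sites with zero
  alternate reads are omitted from that pool's VCF, as a caller would
  omit them. This exercises the "not observed in wild type" filter
  branch.

What it does **not** model: sequencing/alignment error, mapping bias,
repeat regions, GC-coverage coupling, phenotype mis-sorting, or the
hundreds of incidental mutagen-induced substitutions a real screen
carries (an `extra_mutation_per_mb` knob exists but defaults to 0).
Passing tests on simulator output therefore demonstrate the
*statistical* correctness of the windowing, index, filters, and marker
arithmetic — not robustness to real-data artefacts.

## Scale effects to expect

Default simulations use a 2 × 25 Mb genome so a full 20-replicate
recovery study with a coverage sweep runs in seconds. At zebrafish map
density the homozygous region around the locus spans tens of Mb, so on
desk-scale chromosomes the smoothed index typically stays positive
across the whole causative chromosome and the selected interval is the
chromosome itself; the genome-wide maximum still sits on the causative
chromosome and the interval contains the planted locus in essentially
every replicate. For the same reason the homozygous-point density
comparator concentrates per chromosome rather than per Mb bin at this
scale.

One recovery statistic is intrinsically noisy: whether the planted
causative variant survives the segregation filter depends on the
wild-type pool's sampled RO/AO landing strictly inside (1, 4). With a
30-animal sibling pool at 30X the sampled ratio leaves that band in
roughly 15% of replicates (pool-composition plus binomial depth noise
around the expected ratio 2), so the per-replicate retention rate is
≈0.85 — a property of the filter under these pool sizes, not of the
implementation.

## Numerical and interface conventions

* Internal coordinates are 1-based inclusive (VCF convention); BED and
  bedGraph outputs are 0-based half-open. Window centers are the
  midpoints of the 0-based window spans.
* Multi-allelic VCF records are decomposed into one call per alternate
  allele (per-allele AO, shared RO); symbolic alleles and breakends are
  skipped and counted. RO/AO are read from INFO first, then the first
  sample's FORMAT fields.
* Variant matching between pools is exact on (chrom, pos, ref, alt);
  no left-alignment or normalisation is attempted, because both VCFs
  come from one caller on one reference.
* Indices are written with 6 decimals; all randomness flows through a
  single seeded `numpy` generator, and fixed seeds give byte-identical
  outputs.
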