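# bsamap

Mapping-by-sequencing for forward-genetic screens: locate a recessive
causative mutation from pooled whole-genome sequencing of mutant and
wild-type siblings, then shrink the interval by recombinant mapping.

## Who this is for

Labs running chemical-mutagenesis (ENU/EMS) screens in polymorphic model
organisms — zebrafish is the reference use case — who have:

* a VCF for a pool of phenotypically **mutant** larvae and a VCF for a
  pool of phenotypically **wild-type** siblings from the same incross
  (freebayes/POLCA-style records carrying `RO`/`AO` read-observation
  counts),
* the genome's `.fai` index, and optionally gene models (refFlat or
  GFF3), the genome FASTA, and a SIFT score table.

## The statistic

For a recessive mutation, phenotypically mutant F3 larvae are homozygous
at the causative locus and, by linkage, across the surrounding region,
while their siblings stay heterozygous there. `bsamap` counts
heterozygous variant points (both alleles read-supported at a balanced
ratio) in 10-kb windows for each pool and computes, at each window
center C,

```
SNP_index(C) = (Het_wt(C) − Het_mut(C)) / (2 + Het_mut(C))
```

which is large and positive where the mutant pool has lost
heterozygosity. A 750-kb moving average (≈1 cM in zebrafish) smooths
the track; the candidate interval is the region around the genome-wide
maximum, bounded on each side by the smoothed index crossing zero.

Inside the interval, candidate point mutations are filtered for

1. **segregation**: mutant pool RO < 2 and AO ≥ 2; wild-type pool
   heterozygous (1 < RO/AO < 4) or the site not reported,
2. **mutagen signature**: 1–2 bp same-length substitutions,
3. **consequence** (when gene models are supplied): nonsynonymous,
   stop gain/loss, start loss, or splicing, annotated with
   `exonNN: c.<ref><pos><alt>: p.<aa><pos><aa>` notation and optional
   SIFT scores.

Segregating indels in the interval are emitted as PCR-genotypable
mapping markers. Genotyping individual mutant animals at those markers
yields recombination frequencies Rf = recombinants/genotyped, physical
distances Rf × 100 × 0.74 Mb (zebrafish map density), and per-animal
exclusions that refine the interval.

A synthetic-cross simulator (`bsamap simulate`) generates pooled VCF
pairs with known ground truth — background heterozygous SNPs/indels,
one planted causative substitution riding an identical-by-descent
founder haplotype, Haldane-model meioses, and Poisson-depth/binomial
allele read sampling — so the whole pipeline is testable at desk scale.

## Worked example

Simulate a three-clutch, 30-animal-per-pool cross at 30X on a
2 × 25 Mb genome, then map it:

```sh
bsamap simulate --out sim --seed 1
bsamap map --mut sim/mut.vcf --wt sim/wt.vcf --fai sim/genome.fa.fai --out-dir run
```

The run log reports (seed 1):

```
INFO bsamap: mutant VCF: 15769 calls, 0 skipped
INFO bsamap: wild-type VCF: 17395 calls, 0 skipped
INFO bsamap: selected interval chr1:1-25000000 (25.00 Mb, peak 1.591 at 20395000)
INFO bsamap: candidates: 7027 unfiltered, 223 filtered; 24 indel markers
```

The planted mutation (chr1:12,000,000) lies inside the selected
interval; `run/` contains raw and smoothed SNP-index bedGraph tracks,
the interval BED, filtered/unfiltered candidate TSVs, and the marker
TSV. At desk scale the smoothed index usually stays positive across the
whole causative chromosome (linkage in zebrafish spans tens of Mb), so
the interval is the chromosome; on full-size genomes the zero crossings
fall inside chromosomes.

Refinement with a marker genotype table (animals × markers, cells
`M`/`H`/`?`):

```sh
bsamap refine --interval run/interval.bed --genotypes genos.tsv --out-dir run
```

For the classic two-marker layout (35 mutants; 12 recombinant at a
marker at 2.50 Mb, 1 at a marker at 10.71 Mb, interval 2.46–13.87 Mb)
this prints marker distances of 25 and 2 Mb and refines the interval to
10.71–13.87 Mb (3.16 Mb).

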