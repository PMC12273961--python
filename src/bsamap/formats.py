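"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every position is 1-based inclusive (the VCF convention).
BED and bedGraph outputs are 0-based half-open, converted only at the
point of writing.  refFlat input is 0-based half-open and converted to
1-based inclusive on read.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

log = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "GenomeIndex",
    "GeneModel",
    "VcfReadStats",
    "FormatError",
    "read_variant_calls",
    "read_genome_index",
    "read_gene_models",
    "read_sift_table",
    "write_fai",
    "write_bedgraph",
    "write_interval_bed",
    "write_candidates",
    "read_candidates",
    "write_markers",
]

_NUCS = set("ACGTN")


class FormatError(ValueError):
    """Raised for unreadable or malformed input files."""


@dataclass(frozen=True)
class VariantCall:
    """One decomposed VCF record: a single alt allele with its read support.

    ``ro``/``ao`` are the reference- and alternate-supporting read counts
    reported by the upstream caller.  Multi-allelic source records are
    decomposed into one ``VariantCall`` per alt allele carrying the
    per-allele AO and the shared RO.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ro: int
    ao: int
    qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ro < 0 or self.ao < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def length_difference(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenomeIndex:
    """Ordered chromosome names and lengths (from a samtools .fai)."""

    entries: List[Tuple[str, int]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise FormatError("duplicate sequence name in genome index")
        for name, length in self.entries:
            if length < 1:
                raise FormatError(f"sequence {name} has length {length} < 1")

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.entries]

    def length(self, chrom: str) -> int:
        for n, l in self.entries:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(n == chrom for n, _ in self.entries)

    def mappable(self, min_chrom_len: int) -> "GenomeIndex":
        """Sequences at or above ``min_chrom_len`` (drops scaffold noise)."""
        return GenomeIndex([(n, l) for n, l in self.entries if l >= min_chrom_len])


@dataclass
class GeneModel:
    """A transcript model: exon structure plus an optional CDS span.

    All coordinates 1-based inclusive.  ``cds_start``/``cds_end`` are None
    for non-coding models.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.transcript}: overlapping/unsorted exons")
            prev_end = e

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def cds_segments(self) -> List[Tuple[int, int]]:
        """Exon ∩ [cds_start, cds_end], genomic order."""
        if not self.is_coding:
            return []
        segs = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments())


@dataclass
class VcfReadStats:
    """Counters accumulated while streaming a VCF."""

    yielded: int = 0
    skipped_qual: int = 0
    skipped_no_counts: int = 0
    skipped_symbolic: int = 0

    @property
    def skipped(self) -> int:
        return self.skipped_qual + self.skipped_no_counts + self.skipped_symbolic


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in (".", "*")


def read_variant_calls(
    vcf_path: str | os.PathLike,
    min_qual: float = 0.0,
    stats: Optional[VcfReadStats] = None,
) -> Iterator[VariantCall]:
    """Stream decomposed :class:`VariantCall` records from a VCF (plain or bgzip).

    RO/AO are taken from INFO fields named RO/AO, falling back to the first
    sample's FORMAT fields.  Records below ``min_qual`` or lacking both RO
    and AO are skipped and counted in ``stats``; if *no* record in a
    non-empty file carries RO/AO a :class:`FormatError` is raised with a
    remediation hint.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise FormatError(f"cannot parse VCF header of {vcf_path}: {exc}") from exc

    if stats is None:
        stats = VcfReadStats()
    saw_record = False
    try:
        for rec in vcf:
            saw_record = True
            if rec.QUAL is not None and rec.QUAL < min_qual:
                stats.skipped_qual += 1
                continue
            ro, aos = _extract_counts(rec)
            if ro is None or aos is None:
                stats.skipped_no_counts += 1
                continue
            ref = str(rec.REF).upper()
            for i, alt in enumerate(rec.ALT):
                alt = str(alt).upper()
                if _is_symbolic(alt):
                    stats.skipped_symbolic += 1
                    continue
                ao_i = int(aos[i]) if i < len(aos) else 0
                stats.yielded += 1
                yield VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=ref,
                    alt=alt,
                    ro=int(ro),
                    ao=max(ao_i, 0),
                    qual=rec.QUAL,
                )
    finally:
        vcf.close()
    if saw_record and stats.yielded == 0 and stats.skipped_no_counts > 0:
        raise FormatError(
            f"no record in {vcf_path} carries RO/AO read counts (INFO or FORMAT); "
            "this pipeline requires a freebayes/POLCA-style caller that reports "
            "reference/alternate observation counts"
        )


def _extract_counts(rec) -> Tuple[Optional[int], Optional[Sequence[int]]]:
    """RO and per-alt AO from INFO first, then the first sample's FORMAT."""
    ro = rec.INFO.get("RO")
    ao = rec.INFO.get("AO")
    if ro is not None and ao is not None:
        if isinstance(ao, (int, float)):
            ao = (ao,)
        return int(ro), [int(a) for a in ao]
    try:
        ro_f = rec.format("RO")
        ao_f = rec.format("AO")
    except KeyError:
        return None, None
    if ro_f is None or ao_f is None:
        return None, None
    ro0 = int(ro_f[0][0])
    aos = [int(a) for a in ao_f[0]]
    if ro0 < 0 or any(a < -1 for a in aos):  # htslib encodes missing as negative
        return None, None
    return ro0, [max(a, 0) for a in aos]


def read_genome_index(fai_path: str | os.PathLike) -> GenomeIndex:
    """Read a samtools .fai (name, length, offset, linebases, linewidth)."""
    entries: List[Tuple[str, int]] = []
    with open(fai_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{fai_path}:{lineno}: expected >= 2 tab-separated fields")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{fai_path}:{lineno}: non-integer length {parts[1]!r}") from exc
            entries.append((parts[0], length))
    return GenomeIndex(entries)


def write_fai(genome: GenomeIndex, path: str | os.PathLike, linebases: int = 60) -> None:
    """Write a .fai for a (possibly never-materialised) FASTA with ``linebases``-column lines."""
    with open(path, "w") as fh:
        offset = 0
        for name, length in genome.entries:
            offset += len(name) + 2  # ">name\n"
            fh.write(f"{name}\t{length}\t{offset}\t{linebases}\t{linebases + 1}\n")
            n_lines = (length + linebases - 1) // linebases
            offset += length + n_lines


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | os.PathLike, dialect: str = "refflat") -> List[GeneModel]:
    """Read gene models from refFlat TSV or GFF3.

    refFlat coordinates are 0-based half-open and converted to 1-based
    inclusive.  Models failing validation (coordinate inversion, exon count
    mismatch, coding length not a multiple of 3) are skipped with a warning.
    """
    if dialect == "refflat":
        models = list(_read_refflat(path))
    elif dialect == "gff3":
        models = list(_read_gff3(path))
    else:
        raise FormatError(f"unknown gene-model dialect {dialect!r} (expected refflat or gff3)")
    return [m for m in models if _validated(m)]


def _validated(model: GeneModel) -> bool:
    if model.is_coding:
        if not (model.tx_start <= model.cds_start <= model.cds_end <= model.tx_end):
            log.warning("%s: CDS outside transcript span; model skipped", model.transcript)
            return False
        if model.cds_length() % 3 != 0:
            log.warning(
                "%s: coding length %d not a multiple of 3; model skipped",
                model.transcript,
                model.cds_length(),
            )
            return False
    return True


def _read_refflat(path) -> Iterator[GeneModel]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                log.warning("%s:%d: expected 11 refFlat columns, got %d; row skipped", path, lineno, len(f))
                continue
            gene, name, chrom, strand = f[0], f[1], f[2], f[3]
            try:
                tx_start, tx_end = int(f[4]), int(f[5])
                cds_start, cds_end = int(f[6]), int(f[7])
                exon_count = int(f[8])
                starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
                ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            except ValueError:
                log.warning("%s:%d: non-integer coordinate; row skipped", path, lineno)
                continue
            if len(starts) != exon_count or len(ends) != exon_count:
                log.warning("%s:%d: exonCount %d mismatches exon lists; row skipped", path, lineno, exon_count)
                continue
            if tx_start > tx_end or any(s > e for s, e in zip(starts, ends)):
                log.warning("%s:%d: coordinate inversion; row skipped", path, lineno)
                continue
            exons = [(s + 1, e) for s, e in zip(starts, ends)]  # 0-based half-open -> 1-based inclusive
            if cds_start == cds_end:  # non-coding
                cs = ce = None
            else:
                cs, ce = cds_start + 1, cds_end
            try:
                yield GeneModel(gene, name, chrom, strand, exons, cs, ce)
            except ValueError as exc:
                log.warning("%s:%d: %s; row skipped", path, lineno, exc)


def _read_gff3(path) -> Iterator[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    tx_types = [t for t in ("mRNA", "transcript") if t in set(db.featuretypes())]
    for tx_type in tx_types:
        for tx in db.features_of_type(tx_type, order_by="start"):
            exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon", order_by="start")]
            if not exons:
                exons = [(tx.start, tx.end)]
            cds = [(c.start, c.end) for c in db.children(tx, featuretype="CDS", order_by="start")]
            cs, ce = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else (None, None)
            gene = tx.attributes.get("gene_name", tx.attributes.get("Parent", [tx.id]))[0]
            try:
                yield GeneModel(gene, tx.id, tx.seqid, tx.strand, exons, cs, ce)
            except ValueError as exc:
                log.warning("%s: %s; model skipped", tx.id, exc)


# ---------------------------------------------------------------------------
# SIFT


def read_sift_table(path: str | os.PathLike) -> Dict[Tuple[str, int, str, str], float]:
    """TSV with header chrom,pos,ref,alt,sift -> lookup dict.

    Rows with a score outside [0, 1] are rejected with a warning.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "sift"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: SIFT table must have columns {sorted(required)}")
    lookup: Dict[Tuple[str, int, str, str], float] = {}
    for row in df.itertuples(index=False):
        score = float(row.sift)
        if not 0.0 <= score <= 1.0:
            log.warning("%s: SIFT score %s at %s:%s outside [0,1]; row rejected", path, score, row.chrom, row.pos)
            continue
        lookup[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = score
    return lookup


# ---------------------------------------------------------------------------
# outputs

CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ro_mut", "ao_mut", "ro_wt", "ao_wt",
    "gene", "transcript", "region", "effect", "cdna_change", "protein_change", "sift",
]

MARKER_COLUMNS = [
    "chrom", "pos", "ref", "alt", "indel_len_diff", "ro_mut", "ao_mut", "ro_wt", "ao_wt",
]


def write_bedgraph(
    path: str | os.PathLike,
    tracks: Mapping[str, Tuple[Sequence[int], Sequence[float]]],
    window: int,
) -> None:
    """Write windowed values as 4-column bedGraph.

    ``tracks`` maps chrom -> (window centers, values); each window of width
    ``window`` centred at C spans [C - window/2, C + window/2) 0-based
    half-open.  Values are rendered with 6 decimals.
    """
    half = window // 2
    with open(path, "w") as fh:
        for chrom, (centers, values) in tracks.items():
            for c, v in zip(centers, values):
                start = int(c) - half
                fh.write(f"{chrom}\t{start}\t{start + window}\t{v:.6f}\n")


def write_interval_bed(path: str | os.PathLike, chrom: str, left: int, right: int, name: str = "interval") -> None:
    """1-based inclusive [left, right] -> one 0-based half-open BED line."""
    with open(path, "w") as fh:
        fh.write(f"{chrom}\t{left - 1}\t{right}\t{name}\n")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_candidates(path: str | os.PathLike, rows: Iterable[Mapping[str, object]]) -> None:
    """Write candidate rows (dicts keyed by CANDIDATE_COLUMNS) as TSV."""
    _write_tsv(path, CANDIDATE_COLUMNS, rows)


def write_markers(path: str | os.PathLike, rows: Iterable[Mapping[str, object]]) -> None:
    _write_tsv(path, MARKER_COLUMNS, rows)


def _write_tsv(path, columns, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def read_candidates(path: str | os.PathLike) -> List[Dict[str, object]]:
    """Re-read a candidates TSV written by :func:`write_candidates`."""
    out: List[Dict[str, object]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row: Dict[str, object] = {}
            for col, val in zip(header, vals):
                if val == "":
                    row[col] = None
                elif col in ("pos", "ro_mut", "ao_mut", "ro_wt", "ao_wt"):
                    row[col] = int(val)
                elif col == "sift":
                    row[col] = float(val)
                else:
                    row[col] = val
            out.append(row)
    return out
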