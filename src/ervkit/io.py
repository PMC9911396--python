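"""Readers and writers for FASTA, BED, GTF, FASTQ and chromosome-size tables.

Coordinates are converted to 0-based half-open on read (GTF is 1-based
closed on disk) and converted back on write. Parsers are strict: malformed
records raise :class:`FormatError` naming the offending line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .intervals import GenomicInterval, reverse_complement


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class CoordinateError(ValueError):
    """A genomic coordinate falls outside its chromosome."""


_ALPHABET = frozenset("ACGTN")

FEATURE_KINDS = ("gene", "transcript", "exon", "three_prime_utr")
BIOTYPES = ("protein_coding", "lncRNA", "other")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N} (uppercase)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid symbols {sorted(bad)}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-model feature (gene/transcript/exon/3'UTR) with its biotype."""

    interval: GenomicInterval
    feature_kind: str
    gene_id: str
    transcript_id: str = ""
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Parse a multi-record FASTA file; sequences are uppercased."""
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        try:
            records.append(SequenceRecord(header, seq))
        except ValueError as exc:
            raise FormatError(f"{path}:{header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: Union[str, Path]) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED3-BED6; returns (interval, name, score) with BED defaults."""
    out: list[tuple[GenomicInterval, str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append((GenomicInterval(chrom, start, end, strand), name, score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(
    entries: Iterable[tuple[GenomicInterval, str, float]], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for iv, name, score in entries:
            score_str = f"{score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score_str}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_FEATURE_MAP = {
    "gene": "gene",
    "transcript": "transcript",
    "exon": "exon",
    "three_prime_utr": "three_prime_utr",
    "3utr": "three_prime_utr",
    "three_prime_UTR": "three_prime_utr",
}

_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
}


def read_gtf(path: Union[str, Path]) -> list[AnnotationRecord]:
    """Read a GENCODE-style GTF; 1-based closed coordinates become [start-1, end)."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            kind = _FEATURE_MAP.get(feature)
            if kind is None:
                continue  # CDS, start_codon, ... are not used by this pipeline
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            raw_biotype = attr.get("gene_type") or attr.get("gene_biotype") or ""
            biotype = _BIOTYPE_MAP.get(raw_biotype, "other")
            try:
                interval = GenomicInterval(chrom, start - 1, end, strand if strand in "+-" else ".")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(
                AnnotationRecord(interval, kind, gene_id, attr.get("transcript_id", ""), biotype)
            )
    return records


def write_gtf(records: Iterable[AnnotationRecord], path: Union[str, Path]) -> None:
    """Write records back as 1-based closed GTF."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            attrs = f'gene_id "{rec.gene_id}"; gene_type "{rec.biotype}";'
            if rec.transcript_id:
                attrs += f' transcript_id "{rec.transcript_id}";'
            fh.write(
                f"{iv.chrom}\tervkit\t{rec.feature_kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ (via Biopython)


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str = ""


def read_fastq(path: Union[str, Path]) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: Union[str, Path]) -> None:
    records = []
    for r in reads:
        rec = _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        qual = r.qual if r.qual else "I" * len(r.seq)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Chromosome sizes and sequence extraction


def read_chrom_sizes(path: Union[str, Path]) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need chrom and size columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer size") from exc
    return sizes


GenomeLike = Union[Mapping[str, str], Sequence[SequenceRecord]]


def as_genome_dict(genome: GenomeLike) -> Mapping[str, str]:
    if isinstance(genome, Mapping):
        return genome
    return {rec.id: rec.seq for rec in genome}


def extract_sequence(genome: GenomeLike, interval: GenomicInterval) -> str:
    """Genome substring for ``interval``; reverse-complemented on the - strand.

    N bases are preserved; downstream consumers define their own N policy.
    """
    seqs = as_genome_dict(genome)
    if interval.chrom not in seqs:
        raise CoordinateError(f"unknown chromosome {interval.chrom!r}")
    chrom_seq = seqs[interval.chrom]
    if interval.end > len(chrom_seq):
        raise CoordinateError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start : interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub
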