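"""Genomic interval arithmetic.

All coordinates in this package are 0-based half-open (BED convention);
formats using other conventions are converted at the I/O boundary. Strand
"." marks unstranded features and participates in unstranded overlap only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = frozenset({"+", "-", "."})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if stranded and (self.strand == "." or self.strand != other.strand):
            return False
        return self.overlap_len(other) > 0

    def with_strand(self, strand: str) -> "GenomicInterval":
        return replace(self, strand=strand)


def overlap_intervals(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    stranded: bool = False,
) -> list[tuple[int, int, int]]:
    """All (query index, subject index, overlap bp) pairs with >= 1 bp overlap.

    Inputs need not be sorted. In stranded mode only identical non-"."
    strands pair up.
    """
    by_chrom: dict[tuple, list[int]] = {}
    for j, iv in enumerate(subject):
        if stranded and iv.strand == ".":
            continue
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        by_chrom.setdefault(key, []).append(j)

    index: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for key, idxs in by_chrom.items():
        starts = np.array([subject[j].start for j in idxs])
        ends = np.array([subject[j].end for j in idxs])
        order = np.argsort(starts, kind="stable")
        index[key] = (starts[order], ends[order], np.array(idxs)[order])

    pairs: list[tuple[int, int, int]] = []
    for i, q in enumerate(query):
        if stranded and q.strand == ".":
            continue
        key = (q.chrom, q.strand) if stranded else (q.chrom,)
        if key not in index:
            continue
        starts, ends, idxs = index[key]
        hi = int(np.searchsorted(starts, q.end, side="left"))
        if hi == 0:
            continue
        mask = ends[:hi] > q.start
        for s, e, j in zip(starts[:hi][mask], ends[:hi][mask], idxs[:hi][mask]):
            pairs.append((i, int(j), min(q.end, int(e)) - max(q.start, int(s))))
    return pairs


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping/abutting intervals per chromosome (strand dropped)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


class MergedCoverage:
    """Per-chromosome prefix-sum view of a merged interval set.

    Supports vectorised "covered bp within [s, e)" queries, the workhorse of
    base-pair enrichment ratios and their permutation null.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for iv in merge_intervals(intervals):
            self._by_chrom.setdefault(iv.chrom, None)  # type: ignore[arg-type]
        merged = merge_intervals(intervals)
        chroms: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            chroms.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in chroms.items():
            starts = np.array([v.start for v in ivs], dtype=np.int64)
            ends = np.array([v.end for v in ivs], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._by_chrom[chrom] = (starts, ends, cum)

    def covered_before(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Total covered bp in (-inf, pos) for each position."""
        if chrom not in self._by_chrom:
            return np.zeros_like(np.asarray(pos, dtype=np.int64))
        starts, ends, cum = self._by_chrom[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(ends, pos, side="left")
        out = cum[i]
        inside = i < len(starts)
        partial = np.where(inside, pos - starts[np.minimum(i, len(starts) - 1)], 0)
        return out + np.clip(partial, 0, None) * inside

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Covered bp inside each half-open [start, end)."""
        return self.covered_before(chrom, ends) - self.covered_before(chrom, starts)

    def total(self) -> int:
        return int(sum(cum[-1] for _, _, cum in self._by_chrom.values()))
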